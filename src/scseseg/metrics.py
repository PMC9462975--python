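"""Segmentation evaluation: Dice overlap and surface distances.

Surfaces are the 6-connectivity face boundary of a binary mask, with
the grid border counting as background. Distances are Euclidean between
voxel centers, scaled per-axis by the physical spacing when one is
supplied, so ASSD/HD95 are in mm with spacing and in voxel units
without; a report always states its unit.

* ASSD — mean of all nearest-surface distances pooled over both
  directions: (sum_g min_s |s-g| + sum_s min_g |g-s|) / (|dG| + |dS|).
* HD — max of the two directed maxima max_g min_s |g-s|.
* HD95 — the directed maxima replaced by 95th percentiles (linear
  interpolation between order statistics), either per direction then
  maxed ("each", default) or on the pooled distance set ("pooled").
* Dice — 2|G∩S| / (|G| + |S|), in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import EmptySegmentationError, ShapeMismatchError
from .types import LabelMap

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class SurfacePointSet:
    """Voxel coordinates of a mask's face boundary (K, 3) plus spacing."""

    points: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def physical(self) -> np.ndarray:
        return self.points.astype(np.float64) * np.asarray(self.spacing)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ClassMetrics:
    """Metrics for one class, or a note explaining why they are undefined."""

    dice: float | None = None
    assd: float | None = None
    hd95: float | None = None
    note: str | None = None


@dataclass
class MetricReport:
    """Foreground-pooled summary plus per-class one-vs-rest metrics."""

    dice: float | None
    assd: float | None
    hd95: float | None
    per_class: dict[int, ClassMetrics] = field(default_factory=dict)
    unit: str = "voxel"


def _as_mask(mask) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 3:
        raise ShapeMismatchError(f"expected a 3D mask, got {m.ndim}D")
    return m.astype(bool)


def extract_surface(mask, spacing=(1.0, 1.0, 1.0), connectivity: int = 6) -> SurfacePointSet:
    """Foreground voxels with a background (or out-of-grid) neighbor.

    ``connectivity`` selects the neighborhood defining "adjacent":
    6 (faces, default) or 26 (faces+edges+corners).
    """
    m = _as_mask(mask)
    if not m.any():
        raise EmptySegmentationError("cannot extract the surface of an empty mask")
    if connectivity == 6:
        struct = _FACE_STRUCT
    elif connectivity == 26:
        struct = ndimage.generate_binary_structure(3, 3)
    else:
        raise ValueError("connectivity must be 6 or 26")
    interior = ndimage.binary_erosion(m, structure=struct, border_value=0)
    surface = m & ~interior
    return SurfacePointSet(np.argwhere(surface), tuple(float(s) for s in spacing))


def dice(g, s) -> float:
    """Dice overlap 2|G∩S| / (|G| + |S|); symmetric, in [0, 1]."""
    gm, sm = _as_mask(g), _as_mask(s)
    if gm.shape != sm.shape:
        raise ShapeMismatchError(f"mask shapes differ: {gm.shape} vs {sm.shape}")
    tot = int(gm.sum()) + int(sm.sum())
    if tot == 0:
        raise EmptySegmentationError("dice undefined for two empty masks")
    return 2.0 * int((gm & sm).sum()) / tot


def _directed_distances(g, s, spacing):
    """Nearest-surface distances d(G->S) and d(S->G) as 1D arrays."""
    gs = extract_surface(g, spacing).physical()
    ss = extract_surface(s, spacing).physical()
    d_gs = cKDTree(ss).query(gs)[0]
    d_sg = cKDTree(gs).query(ss)[0]
    return d_gs, d_sg


def assd(g, s, spacing=(1.0, 1.0, 1.0)) -> float:
    """Average symmetric surface distance (pooled over both directions)."""
    if _as_mask(g).shape != _as_mask(s).shape:
        raise ShapeMismatchError("mask shapes differ")
    d_gs, d_sg = _directed_distances(g, s, spacing)
    return float((d_gs.sum() + d_sg.sum()) / (len(d_gs) + len(d_sg)))


def hd(g, s, spacing=(1.0, 1.0, 1.0)) -> float:
    """Hausdorff distance: max of the two directed maxima."""
    d_gs, d_sg = _directed_distances(g, s, spacing)
    return float(max(d_gs.max(), d_sg.max()))


def hd95(g, s, spacing=(1.0, 1.0, 1.0), mode: str = "each") -> float:
    """95th-percentile Hausdorff distance.

    mode="each" (default): P95 of each directed set, then the max.
    mode="pooled": P95 of the union of both directed sets.
    """
    d_gs, d_sg = _directed_distances(g, s, spacing)
    if mode == "each":
        return float(max(np.percentile(d_gs, 95), np.percentile(d_sg, 95)))
    if mode == "pooled":
        return float(np.percentile(np.concatenate([d_gs, d_sg]), 95))
    raise ValueError(f"unknown hd95 mode: {mode!r}")


def evaluate(pred: LabelMap, ref: LabelMap, spacing=None) -> MetricReport:
    """Per-class one-vs-rest metrics plus a foreground-pooled summary.

    Background (class 0) is not scored on its own; classes absent from
    both maps are reported with a note rather than a number, as is a
    class that one map lacks (an "empty prediction"/"empty reference"
    has no surface to measure).
    """
    if pred.shape != ref.shape:
        raise ShapeMismatchError(f"shapes differ: {pred.shape} vs {ref.shape}")
    if pred.num_classes != ref.num_classes:
        raise ShapeMismatchError(
            f"class counts differ: {pred.num_classes} vs {ref.num_classes}"
        )
    unit = "mm" if spacing is not None else "voxel"
    sp = tuple(float(v) for v in spacing) if spacing is not None else (1.0, 1.0, 1.0)
    per_class: dict[int, ClassMetrics] = {}
    for c in range(1, ref.num_classes):
        pm_, rm_ = pred.labels == c, ref.labels == c
        has_p, has_r = bool(pm_.any()), bool(rm_.any())
        if not has_p and not has_r:
            per_class[c] = ClassMetrics(note="absent from both maps")
        elif not has_p:
            per_class[c] = ClassMetrics(note="empty prediction")
        elif not has_r:
            per_class[c] = ClassMetrics(note="empty reference")
        else:
            per_class[c] = ClassMetrics(
                dice=dice(rm_, pm_), assd=assd(rm_, pm_, sp), hd95=hd95(rm_, pm_, sp)
            )
    fg_p, fg_r = pred.labels > 0, ref.labels > 0
    if fg_p.any() and fg_r.any():
        summary = MetricReport(
            dice=dice(fg_r, fg_p),
            assd=assd(fg_r, fg_p, sp),
            hd95=hd95(fg_r, fg_p, sp),
            per_class=per_class,
            unit=unit,
        )
    else:
        summary = MetricReport(dice=None, assd=None, hd95=None,
                               per_class=per_class, unit=unit)
    return summary
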