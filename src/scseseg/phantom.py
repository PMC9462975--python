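"""Synthetic knee-MRI-like phantoms for end-to-end testing.

Each phantom is a single-channel 3D volume holding a bright convex
"bone" ellipsoid wrapped by a thin curved "cartilage" shell over a
darker background, with additive Gaussian noise and an optional smooth
multiplicative bias field. Labels are exact (0 background, 1 bone,
2 cartilage by default). Geometry, noise and the dataset splits are
fully determined by integer seeds, so every experiment in the package
is reproducible without any downloads.

The phantoms deliberately keep the property the attention block and the
CRF target — a thin curved structure whose boundary is degraded by
noise — while remaining desk-scale; they do not model MRI physics
(k-space sampling, partial volume, coil inhomogeneity beyond the smooth
bias field).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .errors import ConfigValueError
from .types import TRUE_LABEL, DatasetSplit, LabeledPair, LabelMap, Volume


@dataclass
class PhantomConfig:
    """Geometry, intensity and noise settings of one phantom.

    Intensities are on a nominal [0, 1] scale: background 0.2, bone
    0.9, cartilage 0.55 by default, with additive Gaussian noise of
    sigma 0.05 — visibly noisy but separable, comparable to a decent
    clinical acquisition. ``bone_radius_range`` is a fraction of the
    grid size per axis.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    num_classes: int = 3
    bone_radius_range: tuple[float, float] = (0.18, 0.30)
    shell_thickness: int = 2
    class_means: tuple[float, ...] = (0.2, 0.9, 0.55)
    noise_sigma: float = 0.05
    bias_field: bool = False
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(v) for v in self.shape)  # type: ignore[assignment]
        if len(self.shape) != 3 or any(v % 16 != 0 or v < 16 for v in self.shape):
            raise ConfigValueError("shape: all three sizes must be multiples of 16")
        if self.num_classes < 2:
            raise ConfigValueError("num_classes: must be >= 2")
        if len(self.class_means) != self.num_classes:
            raise ConfigValueError("class_means: need one mean per class")
        if len(set(self.class_means)) != len(self.class_means):
            raise ConfigValueError("class_means: must be pairwise distinct")
        if self.shell_thickness < 1:
            raise ConfigValueError("shell_thickness: must be >= 1")
        if self.noise_sigma < 0:
            raise ConfigValueError("noise_sigma: must be >= 0")
        lo, hi = self.bone_radius_range
        if not (0 < lo <= hi < 0.5):
            raise ConfigValueError("bone_radius_range: need 0 < lo <= hi < 0.5")


def generate_phantom(cfg: PhantomConfig, id: str = "phantom") -> tuple[Volume, LabelMap]:
    """One seeded phantom: ellipsoid bone + cartilage shell + noise."""
    rng = np.random.default_rng(cfg.seed)
    shape = np.asarray(cfg.shape, dtype=float)
    radii = rng.uniform(*cfg.bone_radius_range, size=3) * shape
    # center jitter up to 6% of the grid, bone + shell must stay inside
    center = shape / 2.0 + rng.uniform(-0.06, 0.06, size=3) * shape
    margin = radii + cfg.shell_thickness + 1
    if np.any(center - margin < 0) or np.any(center + margin > shape - 1):
        raise ConfigValueError(
            "bone_radius_range/shell_thickness: shell would exceed the grid"
        )
    grids = np.indices(cfg.shape).astype(float)
    dist2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    bone = dist2 <= 1.0
    # shell: all non-bone voxels within Euclidean distance shell_thickness of bone
    edt = ndimage.distance_transform_edt(~bone)
    shell = (edt <= cfg.shell_thickness) & ~bone
    labels = np.zeros(cfg.shape, dtype=np.int64)
    labels[bone] = 1
    if cfg.num_classes >= 3:
        labels[shell] = 2
    means = np.asarray(cfg.class_means, dtype=np.float64)
    vox = means[labels]
    if cfg.bias_field:
        field = rng.standard_normal(cfg.shape)
        field = ndimage.gaussian_filter(field, sigma=[s / 4 for s in cfg.shape])
        fmax = np.abs(field).max()
        if fmax > 0:
            field = field / fmax * 0.1
        vox = vox * (1.0 + field)
    if cfg.noise_sigma > 0:
        vox = vox + rng.normal(0.0, cfg.noise_sigma, size=cfg.shape)
    volume = Volume(vox, spacing=cfg.spacing, id=id)
    return volume, LabelMap(labels, num_classes=cfg.num_classes)


class SyntheticDataset(NamedTuple):
    """A dataset split plus held-out test pairs and the hidden truth side-car.

    ``hidden_truth`` maps unlabeled-volume ids to their true label maps;
    it exists only so semi- vs fully-supervised comparisons can be
    scored, and is never part of the :class:`DatasetSplit` itself.
    """

    split: DatasetSplit
    test_pairs: list[LabeledPair]
    hidden_truth: dict[str, LabelMap]


def generate_dataset(
    cfg: PhantomConfig,
    n_labeled: int,
    n_unlabeled: int,
    n_test: int,
    seed: int = 0,
) -> SyntheticDataset:
    """Seeded labeled/unlabeled/test phantom collections with unique ids."""
    if min(n_labeled, n_unlabeled, n_test) < 0:
        raise ValueError("counts must be >= 0")
    total = n_labeled + n_unlabeled + n_test
    child_seeds = np.random.SeedSequence(seed).generate_state(total) & 0x7FFFFFFF
    labeled: list[LabeledPair] = []
    unlabeled: list[Volume] = []
    hidden: dict[str, LabelMap] = {}
    test: list[LabeledPair] = []
    idx = 0
    for i in range(n_labeled):
        vol, lm = generate_phantom(replace(cfg, seed=int(child_seeds[idx])), f"labeled-{i:04d}")
        labeled.append(LabeledPair(vol, lm, source=TRUE_LABEL))
        idx += 1
    for i in range(n_unlabeled):
        vol, lm = generate_phantom(replace(cfg, seed=int(child_seeds[idx])), f"unlabeled-{i:04d}")
        unlabeled.append(vol)
        hidden[vol.id] = lm
        idx += 1
    for i in range(n_test):
        vol, lm = generate_phantom(replace(cfg, seed=int(child_seeds[idx])), f"test-{i:04d}")
        test.append(LabeledPair(vol, lm, source=TRUE_LABEL))
        idx += 1
    return SyntheticDataset(DatasetSplit(labeled=labeled, unlabeled=unlabeled), test, hidden)


def corrupt_labels(lm: LabelMap, boundary_flip_rate: float, seed: int = 0) -> LabelMap:
    """Flip boundary-adjacent voxels to a random neighboring class.

    Emulates the rough pseudo-label edges the CRF refinement is meant
    to repair. A voxel is boundary-adjacent when at least one of its 6
    face neighbors carries a different label; each such voxel flips,
    with probability ``boundary_flip_rate``, to a class drawn uniformly
    from its differing neighbors. Interior voxels are never touched.
    """
    if not 0.0 <= boundary_flip_rate <= 1.0:
        raise ValueError("boundary_flip_rate must be in [0, 1]")
    labels = lm.labels.copy()
    if boundary_flip_rate == 0.0:
        return LabelMap(labels, num_classes=lm.num_classes)
    rng = np.random.default_rng(seed)
    shape = labels.shape
    neighbor_labels = []  # per-axis-shifted label grids, padded with self
    for axis in range(3):
        for step in (-1, 1):
            shifted = labels.copy()
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if step == 1:
                dst[axis] = slice(0, shape[axis] - 1)
                src[axis] = slice(1, shape[axis])
            else:
                dst[axis] = slice(1, shape[axis])
                src[axis] = slice(0, shape[axis] - 1)
            shifted[tuple(dst)] = labels[tuple(src)]
            neighbor_labels.append(shifted)
    stack = np.stack(neighbor_labels)  # (6, H, W, S)
    differs = stack != labels[None]
    band = differs.any(axis=0)
    flip = band & (rng.random(shape) < boundary_flip_rate)
    coords = np.argwhere(flip)
    for z, y, x in coords:
        choices = stack[:, z, y, x][differs[:, z, y, x]]
        labels[z, y, x] = rng.choice(np.unique(choices))
    return LabelMap(labels, num_classes=lm.num_classes)
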