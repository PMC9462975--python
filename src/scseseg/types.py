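"""Core in-memory containers shared by every module.

All grids use a single axis convention: ``(H, W, S)`` voxel indices,
0-based. Physical spacing (mm per axis) travels with a :class:`Volume`
but participates only in the evaluation metrics; the network and the
CRF operate in voxel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InvalidLabelError,
    NonFiniteVoxelError,
    NotAVolumeError,
    ShapeMismatchError,
)

TRUE_LABEL = "true_label"
PSEUDO_LABEL = "pseudo_label"


@dataclass
class Volume:
    """A 3D grayscale image grid with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (H, W, S)
        Real-valued intensities; must be finite.
    spacing : tuple of three floats
        Physical voxel size per axis in mm, all > 0.
    id : str
        Free-text identifier, unique within a dataset.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise NotAVolumeError(
                f"expected a 3D grid, got {self.voxels.ndim}D with shape {self.voxels.shape}"
            )
        if self.voxels.size == 0:
            raise NotAVolumeError("volume has a zero-length axis")
        if not np.all(np.isfinite(self.voxels)):
            raise NonFiniteVoxelError(f"volume {self.id!r} contains non-finite intensities")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class LabelMap:
    """A 3D integer class-label grid aligned to a :class:`Volume`."""

    labels: np.ndarray
    num_classes: int = 2

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise NotAVolumeError(
                f"expected a 3D label grid, got {self.labels.ndim}D"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.issubdtype(self.labels.dtype, np.floating) and np.all(
                self.labels == np.round(self.labels)
            ):
                self.labels = self.labels.astype(np.int64)
            else:
                raise InvalidLabelError(
                    f"label grid has non-integer dtype {self.labels.dtype}"
                )
        self.num_classes = int(self.num_classes)
        if self.num_classes < 2:
            raise InvalidLabelError(f"num_classes must be >= 2, got {self.num_classes}")
        lo, hi = int(self.labels.min()), int(self.labels.max())
        if lo < 0 or hi >= self.num_classes:
            raise InvalidLabelError(
                f"labels must lie in [0, {self.num_classes - 1}], found range [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]


@dataclass
class ProbabilityMap:
    """Per-voxel class probabilities, shape (C, H, W, S); rows sum to 1."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 4:
            raise NotAVolumeError(
                f"expected a (C, H, W, S) probability stack, got {self.probs.ndim}D"
            )
        if self.probs.min() < -1e-9 or self.probs.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.probs.sum(axis=0)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("per-voxel class probabilities must sum to 1 within 1e-6")

    @property
    def num_classes(self) -> int:
        return self.probs.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.probs.shape[1:]  # type: ignore[return-value]

    def argmax_labels(self) -> LabelMap:
        """Per-voxel most probable class (ties -> lowest class index)."""
        return LabelMap(
            np.argmax(self.probs, axis=0).astype(np.int64), num_classes=self.num_classes
        )


@dataclass
class LabeledPair:
    """A volume together with its labels; ``source`` records provenance."""

    volume: Volume
    labels: LabelMap
    source: str = TRUE_LABEL

    def __post_init__(self) -> None:
        if self.source not in (TRUE_LABEL, PSEUDO_LABEL):
            raise ValueError(f"source must be {TRUE_LABEL!r} or {PSEUDO_LABEL!r}")
        if self.volume.shape != self.labels.shape:
            raise ShapeMismatchError(
                f"volume shape {self.volume.shape} != label shape {self.labels.shape}"
            )


@dataclass
class DatasetSplit:
    """Labeled set D_L, unlabeled set D_U and the self-training round counter."""

    labeled: list[LabeledPair] = field(default_factory=list)
    unlabeled: list[Volume] = field(default_factory=list)
    round_index: int = 0

    def __post_init__(self) -> None:
        for pair in self.labeled:
            if pair.source != TRUE_LABEL:
                raise ValueError("DatasetSplit.labeled must contain only true-labeled pairs")
        labeled_ids = {p.volume.id for p in self.labeled}
        unlabeled_ids = {v.id for v in self.unlabeled}
        clash = labeled_ids & unlabeled_ids
        if clash:
            raise ValueError(f"volumes present in both labeled and unlabeled sets: {sorted(clash)}")
        if self.round_index < 0:
            raise ValueError("round_index must be >= 0")
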