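"""NIfTI-1 reading and writing for volumes and label maps.

NIfTI is the single supported on-disk format: volumes are stored with a
floating dtype, label maps with an unsigned integer dtype. Spacing is
carried in the header zooms; orientation is a plain diagonal affine
(no resampling or reorientation is ever performed).
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import InvalidLabelError, NonFiniteVoxelError, NotAVolumeError
from .types import LabelMap, Volume


def _load(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return nib.load(path)


def _check_3d(data: np.ndarray, path: Path) -> np.ndarray:
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise NotAVolumeError(
            f"{path} is not a 3D volume (got {data.ndim}D data of shape {data.shape}); "
            "multi-channel/4D input is unsupported"
        )
    return data


def read_volume(path: str | Path) -> Volume:
    """Read a single-channel 3D NIfTI file into a :class:`Volume`.

    Intensities are returned in the stored dtype, bit for bit; spacing
    comes from the header zooms. The volume id is the filename stem.
    """
    path = Path(path)
    img = _load(path)
    data = _check_3d(np.asanyarray(img.dataobj), path)
    if not np.all(np.isfinite(data)):
        raise NonFiniteVoxelError(f"{path} contains non-finite voxels")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    stem = path.name
    for suffix in (".gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    return Volume(voxels=data, spacing=spacing, id=stem)


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a :class:`Volume` as NIfTI; dtype is preserved for floats."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = np.asarray(vol.voxels)
    if not np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, os.fspath(path))


def read_labels(path: str | Path, num_classes: int | None = None) -> LabelMap:
    """Read a label map; non-integer voxel data is rejected, never rounded.

    ``num_classes`` defaults to ``max(label) + 1`` (at least 2).
    """
    path = Path(path)
    img = _load(path)
    data = _check_3d(np.asanyarray(img.dataobj), path)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(np.isfinite(data)) or np.any(data != np.round(data)):
            raise InvalidLabelError(f"{path} does not hold an integer label grid")
        data = data.astype(np.int64)
    if num_classes is None:
        num_classes = max(int(data.max()) + 1, 2)
    return LabelMap(labels=data.astype(np.int64), num_classes=num_classes)


def write_labels(lm: LabelMap, path: str | Path, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write a label map as unsigned-integer NIfTI."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    labels = np.asarray(lm.labels)
    if labels.min() < 0:
        raise InvalidLabelError("labels must be non-negative")
    dtype = np.uint8 if lm.num_classes <= 256 else np.uint16
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(labels.astype(dtype), affine)
    img.header.set_zooms(tuple(spacing))
    nib.save(img, os.fspath(path))


def read_probability(path: str | Path):
    """Read a 4D NIfTI probability stack stored as (H, W, S, C) into (C, H, W, S)."""
    from .types import ProbabilityMap

    path = Path(path)
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise NotAVolumeError(f"{path} is not a 4D probability stack")
    return ProbabilityMap(np.moveaxis(data, 3, 0))


def write_probability(pm, path: str | Path, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write a probability stack as 4D NIfTI with classes on the last axis."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = np.moveaxis(np.asarray(pm.probs, dtype=np.float32), 0, 3)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), os.fspath(path))
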