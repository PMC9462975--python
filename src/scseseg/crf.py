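"""Fully-connected conditional random field over voxels.

The energy of a labeling f is

    E(f) = sum_i psi_u(f_i) + sum_{i<j} mu(f_i, f_j) * k(i, j)

with unary potentials psi_u = -log P from the network's softmax output,
Potts compatibility mu (0 for equal labels, 1 otherwise) and a
label-independent two-kernel Gaussian pairwise term

    k(i, j) = w1 * exp(-|x_i - x_j|^2 / (2 sa^2) - |y_i - y_j|^2 / (2 sb^2))
            + w2 * exp(-|x_i - x_j|^2 / (2 sg^2))

where x are voxel positions and y are [0,1]-normalized intensities.
Inference is parallel mean-field; the dense O(N^2) form is exact and
intended for small volumes, while a truncated-neighborhood form
(``neighborhood_radius``) scales to full phantoms. An exhaustive
enumeration of all labelings serves as a global-minimum oracle on tiny
instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigValueError, InstanceTooLargeError, SelfPairError, ShapeMismatchError
from .types import LabelMap, ProbabilityMap, Volume


@dataclass
class CrfConfig:
    """Kernel weights/scales and inference settings.

    omega1/omega2 weight the appearance and smoothness kernels;
    sigma_alpha (voxels) and sigma_beta (normalized intensity) scale the
    appearance kernel, sigma_gamma (voxels, default 1) the smoothness
    kernel. ``iterations`` is the number of mean-field rounds (default
    5). ``unary_clamp`` bounds -log P at P = 0. ``neighborhood_radius``
    of None selects the exact dense form (guarded by ``dense_limit``
    voxels); an integer radius selects the truncated approximation.
    """

    omega1: float = 1.0
    omega2: float = 1.0
    sigma_alpha: float = 3.0
    sigma_beta: float = 0.1
    sigma_gamma: float = 1.0
    iterations: int = 5
    unary_clamp: float = 50.0
    neighborhood_radius: int | None = None
    dense_limit: int = 4096

    def __post_init__(self) -> None:
        if self.omega1 < 0 or self.omega2 < 0:
            raise ConfigValueError("omega1/omega2: kernel weights must be >= 0")
        for name in ("sigma_alpha", "sigma_beta", "sigma_gamma"):
            if getattr(self, name) <= 0:
                raise ConfigValueError(f"{name}: must be > 0")
        if self.iterations < 0:
            raise ConfigValueError("iterations: must be >= 0")
        if self.neighborhood_radius is not None and self.neighborhood_radius < 1:
            raise ConfigValueError("neighborhood_radius: must be >= 1 or None")


@dataclass
class UnaryField:
    """Per-voxel, per-class label costs psi_u, shape (C, H, W, S)."""

    potentials: np.ndarray

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=np.float64)
        if self.potentials.ndim != 4:
            raise ShapeMismatchError("unary potentials must be (C, H, W, S)")
        if not np.all(np.isfinite(self.potentials)) or self.potentials.min() < 0:
            raise ValueError("unary potentials must be finite and >= 0")


def normalized_intensity(vol: Volume) -> np.ndarray:
    """Min-max normalize intensities to [0, 1] (constant volume -> zeros)."""
    x = np.asarray(vol.voxels, dtype=np.float64)
    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        return (x - lo) / (hi - lo)
    return np.zeros_like(x)


def unary_from_probability(pm: ProbabilityMap, clamp: float = 50.0) -> UnaryField:
    """psi_u = -log P elementwise, with P < e^-clamp clamped so psi_u <= clamp."""
    p = np.maximum(pm.probs, np.exp(-clamp))
    return UnaryField(-np.log(p))


def pairwise_kernel(i, j, vol: Volume, cfg: CrfConfig) -> float:
    """Label-independent Gaussian kernel value k(i, j) for two voxel indices."""
    i = tuple(int(v) for v in i)
    j = tuple(int(v) for v in j)
    if i == j:
        raise SelfPairError(f"pairwise kernel undefined for a voxel paired with itself: {i}")
    y = normalized_intensity(vol)
    pd = float(sum((a - b) ** 2 for a, b in zip(i, j)))
    idiff = float(y[i] - y[j]) ** 2
    appearance = cfg.omega1 * np.exp(
        -pd / (2.0 * cfg.sigma_alpha ** 2) - idiff / (2.0 * cfg.sigma_beta ** 2)
    )
    smoothness = cfg.omega2 * np.exp(-pd / (2.0 * cfg.sigma_gamma ** 2))
    return float(appearance + smoothness)


def _dense_kernel_matrix(vol: Volume, cfg: CrfConfig) -> np.ndarray:
    """Full (N, N) kernel matrix with zero diagonal, voxels in C-order."""
    shape = vol.shape
    pos = np.indices(shape).reshape(3, -1).T.astype(np.float64)
    y = normalized_intensity(vol).reshape(-1, 1)
    pd = cdist(pos, pos, "sqeuclidean")
    idist = cdist(y, y, "sqeuclidean")
    k = cfg.omega1 * np.exp(
        -pd / (2.0 * cfg.sigma_alpha ** 2) - idist / (2.0 * cfg.sigma_beta ** 2)
    ) + cfg.omega2 * np.exp(-pd / (2.0 * cfg.sigma_gamma ** 2))
    np.fill_diagonal(k, 0.0)
    return k


def total_energy(labels: LabelMap, unary: UnaryField, vol: Volume, cfg: CrfConfig) -> float:
    """Exact E(f): selected unaries plus the Potts-weighted kernel over i < j.

    Sums over all unordered voxel pairs; intended for small instances.
    """
    if labels.shape != vol.shape or unary.potentials.shape[1:] != vol.shape:
        raise ShapeMismatchError(
            f"labels {labels.shape}, unary {unary.potentials.shape[1:]} and "
            f"volume {vol.shape} must agree"
        )
    f = labels.labels.reshape(-1)
    n = f.size
    uflat = unary.potentials.reshape(unary.potentials.shape[0], -1)
    e = float(uflat[f, np.arange(n)].sum())
    k = _dense_kernel_matrix(vol, cfg)
    diff = (f[:, None] != f[None, :])
    iu = np.triu_indices(n, k=1)
    e += float((k[iu] * diff[iu]).sum())
    return e


def mean_field_refine(
    pm: ProbabilityMap, vol: Volume, cfg: CrfConfig
) -> tuple[ProbabilityMap, LabelMap]:
    """Mean-field CRF inference starting from the network's probabilities.

    Runs ``cfg.iterations`` parallel update rounds of
    ``Q_i(l) ∝ exp(-psi_u,i(l) - sum_{j≠i} k(i,j) (1 - Q_j(l)))``
    and returns the refined probabilities and their argmax labeling.
    """
    if pm.spatial_shape != vol.shape:
        raise ShapeMismatchError(
            f"probability map {pm.spatial_shape} and volume {vol.shape} must agree"
        )
    ncls = pm.num_classes
    shape = vol.shape
    psi = unary_from_probability(pm, cfg.unary_clamp).potentials
    if cfg.neighborhood_radius is None:
        n = int(np.prod(shape))
        if n > cfg.dense_limit:
            raise InstanceTooLargeError(
                f"{n} voxels exceed the dense limit of {cfg.dense_limit}; "
                "set neighborhood_radius to use the truncated approximation"
            )
        q = _mean_field_dense(pm, vol, psi, cfg)
    else:
        q = _mean_field_truncated(pm, vol, psi, cfg)
    refined = ProbabilityMap(q.reshape(ncls, *shape))
    return refined, refined.argmax_labels()


def _mean_field_dense(pm, vol, psi, cfg) -> np.ndarray:
    ncls = pm.num_classes
    k = _dense_kernel_matrix(vol, cfg)
    ksum = k.sum(axis=1)
    q = pm.probs.reshape(ncls, -1).copy()
    uflat = psi.reshape(ncls, -1)
    for _ in range(cfg.iterations):
        # Potts message: m_i(l) = sum_j k_ij (1 - Q_j(l))
        msg = ksum[None, :] - q @ k.T
        logits = -uflat - msg
        logits -= logits.max(axis=0, keepdims=True)
        q = np.exp(logits)
        q /= q.sum(axis=0, keepdims=True)
    return q


def _neighborhood_offsets(radius: int):
    offs = []
    for d in itertools.product(range(-radius, radius + 1), repeat=3):
        if d == (0, 0, 0):
            continue
        if d[0] ** 2 + d[1] ** 2 + d[2] ** 2 <= radius ** 2:
            offs.append(d)
    return offs


def _shift_slices(shape, off):
    """Slices (dst, src) so that dst gathers values from voxel + off."""
    dst, src = [], []
    for size, o in zip(shape, off):
        if o >= 0:
            dst.append(slice(0, size - o))
            src.append(slice(o, size))
        else:
            dst.append(slice(-o, size))
            src.append(slice(0, size + o))
    return tuple(dst), tuple(src)


def _mean_field_truncated(pm, vol, psi, cfg) -> np.ndarray:
    ncls = pm.num_classes
    shape = vol.shape
    y = normalized_intensity(vol)
    offsets = _neighborhood_offsets(cfg.neighborhood_radius)
    # per-offset spatial weights and per-voxel intensity terms
    kernels = []
    for off in offsets:
        pd = float(off[0] ** 2 + off[1] ** 2 + off[2] ** 2)
        dst, src = _shift_slices(shape, off)
        idiff = np.zeros(shape)
        idiff[dst] = (y[dst] - y[src]) ** 2
        k = cfg.omega1 * np.exp(
            -pd / (2.0 * cfg.sigma_alpha ** 2) - idiff / (2.0 * cfg.sigma_beta ** 2)
        ) + cfg.omega2 * np.exp(-pd / (2.0 * cfg.sigma_gamma ** 2))
        mask = np.zeros(shape)
        mask[dst] = 1.0
        kernels.append((off, k * mask, dst, src))
    q = pm.probs.copy()
    for _ in range(cfg.iterations):
        msg = np.zeros((ncls,) + shape)
        for off, k, dst, src in kernels:
            contrib = np.zeros((ncls,) + shape)
            contrib[(slice(None),) + dst] = 1.0 - q[(slice(None),) + src]
            msg += k[None] * contrib
        logits = -psi - msg
        logits -= logits.max(axis=0, keepdims=True)
        q = np.exp(logits)
        q /= q.sum(axis=0, keepdims=True)
    return q.reshape(ncls, -1)


def exhaustive_map(unary: UnaryField, vol: Volume, cfg: CrfConfig) -> LabelMap:
    """Globally optimal labeling by enumerating every assignment.

    Feasible only for C^N <= 2^20; ties resolve to the lexicographically
    smallest labeling (voxels in C-order, label values ascending).
    """
    ncls = unary.potentials.shape[0]
    shape = vol.shape
    n = int(np.prod(shape))
    if ncls ** n > 2 ** 20:
        raise InstanceTooLargeError(
            f"{ncls}^{n} labelings exceed the enumeration limit of 2^20"
        )
    m = ncls ** n
    codes = np.arange(m)
    labelings = np.empty((m, n), dtype=np.int8)
    for v in range(n):
        labelings[:, v] = (codes // (ncls ** (n - 1 - v))) % ncls
    uflat = unary.potentials.reshape(ncls, -1)
    energy = uflat[labelings, np.arange(n)[None, :]].sum(axis=1)
    k = _dense_kernel_matrix(vol, cfg)
    for i in range(n):
        for j in range(i + 1, n):
            energy += k[i, j] * (labelings[:, i] != labelings[:, j])
    best = int(np.argmin(energy))  # argmin returns the first = lex smallest
    return LabelMap(labelings[best].reshape(shape).astype(np.int64), num_classes=ncls)
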