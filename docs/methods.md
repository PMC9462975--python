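# Methods

## Problem

Dense voxel-wise segmentation of 3D grayscale volumes — the motivating
setting is knee MRI, where a bright bone body is wrapped by a thin,
curved cartilage layer — with very few expert-labeled volumes and a
larger pool of unlabeled ones. The toolkit combines three ingredients:
an attention-augmented 3D U-Net, a self-training loop that converts
unlabeled volumes into pseudo-labels, and a fully-connected CRF that
cleans pseudo-label boundaries before they re-enter training.

## Segmentation network

A four-level 3D U-Net. Each encoder level applies two 3×3×3
convolutions with ReLU, then 2×2×2 max pooling (stride 2); channel
width starts at `base_channels` and doubles per level; a two-conv
bottleneck sits below the fourth pool. Each decoder level upsamples
with a stride-2 transposed convolution, concatenates the same-resolution
encoder feature map, applies one scSE attention block to the
concatenation, then two 3×3×3 conv+ReLU. A 1×1×1 convolution and a
per-voxel softmax produce class probabilities. There are exactly four
attention blocks, one per decoder level. There are no normalization
layers in the default architecture.

**scSE block.** Channel gate: the feature map is reduced over its
spatial extent by a global max pool and a global average pool in
parallel; each pooled C-vector passes its own C → C/r → C bottleneck
(ReLU between and after; r = `se_reduction`, default 2, one independent
bottleneck per branch), the two branch outputs are added, and a sigmoid
yields a per-channel gate in (0,1). The max-pool branch exists to
retain edge/texture responses that averaging washes out. Spatial gate:
a 1×1×1 convolution to one channel plus sigmoid yields a per-voxel
gate. The input is multiplied by each gate and the two gated maps are
fused — elementwise addition by default (with zeroed block parameters
both gates are exactly ½ and add-fusion is the identity, which makes
the block's algebra directly testable), or elementwise maximum via
`se_fusion="max"`.

**Placement.** Descriptions of where the block sits are ambiguous
between "end of the skip connection" and "before the upsampling
layer"; this implementation applies it to the concatenated
skip+upsampled features, before the decoder convolutions.

**Implementation.** The network, its backpropagation and the Adam
optimizer are implemented directly in NumPy (float32, im2col + GEMM
convolutions, per-layer reusable buffers). At the intended scale —
base 8 channels, 32³ volumes — a training step takes roughly 0.3 s on
one CPU core, and the backward pass is verified against central finite
differences in float64. All randomness (initialization, shuffling)
derives from explicit integer seeds; repeated runs are bit-identical.

**Input normalization.** Each volume is normalized per volume before
entering the network; the default is a z-score (zero mean, unit
variance). Without normalization layers in the architecture,
zero-centered inputs matter: with [0,1] min-max inputs, training on
strongly class-imbalanced volumes sat in an all-background regime for
tens of epochs before recovering, while z-scored inputs converge
directly. `minmax` and `none` modes remain available.

**Training.** Adam on voxel-wise categorical cross-entropy. The
published reference settings (learning rate 1e-4, 150 epochs, batch
size 1, five unlabeled subsets, five CRF iterations) are the config
defaults. The desk-scale experiment profile (below) uses a higher
learning rate because its runs are two orders of magnitude shorter.

## Self-training loop

1. Train the network on the labeled set D_L (the "initial phase").
2. Randomly partition the unlabeled set into k near-equal subsets
   (default k = 5; the partition is seeded, disjoint, covering, sizes
   differing by at most one).
3. Each round r: predict subset r; optionally refine each probability
   map with the CRF; take the per-voxel argmax as a pseudo-label; append
   the pseudo-labeled pairs to the training set (true-labeled pairs are
   never replaced — an id collision is an error); retrain, warm-started
   from the current weights by default (`from_scratch` rebuilds).
4. After k rounds every unlabeled volume carries a pseudo-label.

Pseudo-labels are never revisited in later rounds; the training set
grows monotonically. This preserves the known error-amplification risk
of self-training: a wrong early pseudo-label persists. The experiments
below show this concretely — with an under-trained initial model the
loop collapses to the majority class — which is why the initial phase
must be trained to convergence before the first pseudo round. A
volume-level confidence filter exists (`min_confidence` drops volumes
whose mean winning probability is below threshold) but is off by
default: faithfully, every prediction is added.

## Fully-connected CRF

Energy over labelings f of a volume with intensities y and voxel
positions x:

    E(f) = Σ_i ψ_u(f_i) + Σ_{i<j} μ(f_i, f_j) k(i, j)
    ψ_u  = −log P           (clamped at `unary_clamp`, default 50)
    k(i,j) = ω₁ exp(−‖x_i−x_j‖²/2σ_α² − (y_i−y_j)²/2σ_β²)
           + ω₂ exp(−‖x_i−x_j‖²/2σ_γ²)

with Potts compatibility μ (0 for equal labels, 1 otherwise). A
sentence in the source text assigns μ the value 0 when labels differ,
which contradicts its own description of the pairwise term penalizing
similar voxels with different labels; the Potts reading is used.
Intensities are min-max normalized to [0,1] so σ_β has a fixed scale.
Defaults: ω₁ = ω₂ = 1, σ_α = 3 voxels, σ_β = 0.1, σ_γ = 1 voxel
(only σ_γ is published), 5 mean-field iterations.

Inference is parallel mean-field: Q is initialized to the softmax
probabilities and updated as
Q_i(l) ∝ exp(−ψ_u,i(l) − Σ_{j≠i} k(i,j)(1 − Q_j(l))). The dense O(N²)
form is exact and guarded by a voxel-count limit (default 4096); a
truncated-neighborhood form (`neighborhood_radius`, Euclidean, in
voxels) handles full volumes and equals the dense form when the radius
covers the grid. An exhaustive enumerator over all C^N ≤ 2²⁰ labelings
(ties → lexicographically smallest) serves as the global-optimum
oracle in tests.

Two behaviors worth knowing. First, with an unnormalized truncated
neighborhood the pairwise message mass per voxel is roughly
ω · Σ_offsets k(offset) (≈ 40·ω at radius 2), so large ω makes the
smoothness term dominate the unaries and can delete structures thinner
than the neighborhood — the classic thin-structure failure of Potts
smoothing. Second, whether the CRF helps depends on the probability
maps: applied to the confident output of a converged network it
sharpens boundaries (measured below), applied to a half-trained
network's diffuse output it erases the weakest class.

## Evaluation metrics

Surfaces are the 6-connectivity face boundary (grid border counts as
background). Distances are Euclidean between voxel centers, scaled
per-axis by spacing when given; reports state their unit (mm with
spacing, voxels without).

* Dice = 2|G∩S| / (|G|+|S|).
* ASSD = pooled mean of nearest-surface distances over both directions.
* HD = max of the two directed maxima; HD95 replaces each directed
  maximum by the 95th percentile (linear interpolation between order
  statistics) and takes the max of the two — a "pooled" percentile
  over the union is available as an alternative convention.

Empty masks raise errors rather than return sentinel zeros; in
`evaluate`, a class missing from one map is reported with an
explanatory note ("empty prediction" / "empty reference" / "absent
from both maps") instead of a number. All three distances are tested
to 1e-9 against independent all-pairs brute-force implementations.

## Synthetic phantoms

Each phantom is a 32³ (configurable, multiples of 16) volume holding a
randomized ellipsoid "bone" (per-axis radii 18–30 % of the grid, small
center jitter), wrapped by a "cartilage" shell of all non-bone voxels
within 2 voxels Euclidean distance of the bone (equivalently:
ball-dilation of the bone minus the bone, which is the independent
oracle used in tests). Intensities are class means (background 0.2,
bone 0.9, cartilage 0.55 on a nominal [0,1] scale) plus Gaussian noise
(σ = 0.05), optionally modulated by a ±10 % smooth multiplicative bias
field. Labels are exact. `corrupt_labels` flips boundary-adjacent
voxels to a random differing-neighbor class with a given probability,
emulating rough pseudo-label edges for the CRF-repair tests.

The phantoms keep the method's essential difficulty — a thin curved
structure under noise — at desk scale. They do not model MRI physics
(k-space sampling, partial volume, coil profiles), anatomy, or
inter-scanner variability, so passing tests demonstrate the
correctness and internal behavior of the pipeline, not clinical-grade
performance on real knee MRI.

`generate_dataset` derives one integer seed per phantom from a master
seed and returns the labeled/unlabeled split, held-out test pairs, and
a side-car dict mapping unlabeled ids to their true labels, used only
for scoring — the split object itself never carries them.

## End-to-end experiment (scaled-down)

Conditions (`PhantomExperimentConfig`): 4 labeled + 16 unlabeled +
8 test phantoms at 32³; network base 8 channels; initial phase 70
epochs; 4 unlabeled subsets, 10 epochs per round, warm-started; CRF on
with default kernels and neighborhood radius 2; Adam at 3e-3. The
labeled-only baseline is trained with exactly the initial phase's
recipe (same 70 epochs, same data) — the same control the reference
protocol uses, where the fully-supervised comparison model receives
the same per-model schedule rather than the loop's cumulative budget.
A third arm corrupts a fresh phantom's labels at boundary-flip rate
0.5, softens them to probabilities (0.9 on the stated class), refines
with the CRF, and compares foreground dice before/after.

The epoch counts were sized so one full run takes ~5 minutes on one
CPU core; 70 initial epochs is where the thin-shell class is reliably
learned across seeds (at 40–60 epochs some initializations still
segment only bone, and the loop then freezes that state into its
pseudo-labels).

Typical results (seeded; recomputed by `scripts/acceptance.py` and the
acceptance tests, never hard-coded): baseline foreground dice ≈ 0.97,
self-training ≈ 0.99 (the pseudo-labeled rounds sharpen rather than
degrade), CRF repair of corrupted boundaries ≈ 0.87 → 0.99.

## Numerical choices and degenerate inputs

* float32 network arithmetic; float64 for CRF energies and metrics.
* Softmax and sigmoid are computed in numerically stabilized forms.
* Unary clamp replaces −log 0 by a finite cost (default 50).
* Mean-field argmax ties resolve to the lowest class index; the
  exhaustive oracle resolves energy ties to the lexicographically
  smallest labeling.
* A constant volume normalizes to all-zeros (z-score and min-max).
* Label maps must be integer-valued; fractional grids are rejected,
  never rounded.

## Known limitations

* Dense CRF inference is exact only up to the voxel-count guard; the
  truncated form ignores interactions beyond its radius.
* No patch-based inference: volume dimensions must be divisible by 16.
* Single-channel volumes only; no DICOM, resampling or registration.
* Self-training never re-labels: early pseudo-label errors persist by
  design, matching the reference procedure.
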