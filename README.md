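# scseseg

Semi-supervised 3D segmentation for volumetric grayscale images (the
motivating case is knee MRI, where a thin curved cartilage layer wraps
a bright bone body and expert labels are scarce). The toolkit provides:

* **3D scSE-UNet** — a four-level 3D U-Net whose decoder applies, at
  each skip connection, a concurrent spatial & channel
  squeeze-excitation attention block with a dual channel gate (global
  max pool and global average pool in parallel, each through its own
  C → C/r → C bottleneck, added and squashed by a sigmoid). Implemented
  in pure NumPy with hand-written backpropagation and Adam, so it runs
  anywhere and is bit-reproducible from a seed.
* **Self-training** — train on the labeled set D_L = {(X_L, Y_L)},
  partition the unlabeled set D_U into k subsets, and per round:
  predict a subset, refine with the CRF, add the results as
  pseudo-labels (D^{i+1}_train = D^i_train + D^i_U), retrain.
* **Dense CRF refinement** — minimizes
  E(f) = Σᵢ ψ_u(fᵢ) + Σ_{i<j} μ(fᵢ,fⱼ)·k(i,j) with unaries
  ψ_u = −log P from the softmax output, Potts μ, and a two-kernel
  Gaussian pairwise term (appearance: position + intensity;
  smoothness: position only) by mean-field iteration; exact dense form
  for small volumes, truncated-neighborhood form for full ones, and an
  exhaustive global-minimum oracle for tiny instances.
* **Metrics** — Dice, average symmetric surface distance (ASSD) and
  95th-percentile Hausdorff distance (HD95) over 6-connectivity face
  boundaries, validated to 1e-9 against brute-force oracles.
* **Phantoms** — a seedable generator of bone-plus-cartilage-shell
  test volumes, so the full pipeline runs end-to-end with no data
  downloads.

## Worked example

```python
from scseseg.experiment import PhantomExperimentConfig, run_phantom_experiment

res = run_phantom_experiment(PhantomExperimentConfig(seed=0))
print(f"baseline  dice {res['baseline_dice']:.4f}")
print(f"selftrain dice {res['selftrain_dice']:.4f}")
print(f"CRF repair {res['dice_corrupted']:.4f} -> {res['dice_repaired']:.4f}")
```

This generates 4 labeled + 16 unlabeled + 8 test phantoms (32³),
trains a labeled-only baseline (70 epochs), runs the self-training
loop (4 subsets, 10 epochs/round, CRF-refined pseudo-labels), scores
both on the held-out phantoms, and repairs a deliberately corrupted
labeling with the CRF. It takes a few minutes on one CPU core and
prints:

```
baseline  dice 0.9761
selftrain dice 0.9979
CRF repair 0.8691 -> 0.9879
```

Read: the baseline already segments the phantoms well (foreground Dice
0.976); adding CRF-refined pseudo-labels from the 16 unlabeled volumes
sharpens it further (0.998); and mean-field refinement recovers most
of the boundary damage injected at flip rate 0.5 (0.869 → 0.988).

The same pipeline is scriptable from the shell:

```sh
scseseg simulate --out data --n-labeled 4 --n-unlabeled 16 --n-test 8 --seed 0
scseseg selftrain --config cfg.yaml --labeled data/labeled \
        --unlabeled data/unlabeled --heldout data/test --out run
scseseg predict --checkpoint run/checkpoint.npz --in data/test/volumes --out run/preds
scseseg evaluate --pred run/preds --ref data/test/labels --out report.json
```

plus `train`, `predict` and `refine` for the individual stages. Every
command writes a JSON manifest (config + seed + versions) beside its
outputs. Config files are strict YAML: unknown keys are errors, and
unspecified keys take the reference defaults (learning rate 1e-4,
150 epochs, batch size 1, Adam, 5 subsets, 5 CRF iterations).

See `docs/methods.md` for the model, the energy function, parameter
meanings and the design decisions.

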