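"""Self-training semi-supervised segmentation loop.

Round 0 trains the network on the labeled set alone. The unlabeled set
is randomly partitioned into k near-equal subsets; each round predicts
one subset, optionally refines the predictions with the dense CRF,
flags the results as pseudo-labels, appends them to the training set
(true labels are never replaced) and retrains — warm-started by
default, or from scratch. After k rounds every unlabeled volume has
received a pseudo-label. Pseudo-labels are never revisited in later
rounds; as the set grows monotonically, an early mis-segmentation can
therefore persist, which is exactly the failure mode the CRF
refinement is meant to dampen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .crf import CrfConfig, mean_field_refine
from .errors import ConfigValueError, IdCollisionError
from .metrics import MetricReport, evaluate
from .network import (
    NetworkConfig,
    SegmentationNetwork,
    TrainConfig,
    build_network,
    train_supervised,
)
from .types import PSEUDO_LABEL, TRUE_LABEL, DatasetSplit, LabeledPair, Volume


@dataclass
class SelfTrainingConfig:
    """Loop control: subset count, rounds, retraining and CRF settings."""

    num_subsets: int = 5
    rounds: Optional[int] = None  # defaults to num_subsets
    initial_epochs: Optional[int] = None  # epochs for the labeled-only phase; defaults to train.epochs
    retrain_mode: str = "continue"
    use_crf: bool = True
    min_confidence: Optional[float] = None  # off by default: every prediction is added
    crf: CrfConfig = field(default_factory=CrfConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_subsets < 1:
            raise ConfigValueError("num_subsets: must be >= 1")
        if self.rounds is None:
            self.rounds = self.num_subsets
        if not 0 <= self.rounds <= self.num_subsets:
            raise ConfigValueError("rounds: must be between 0 and num_subsets")
        if self.retrain_mode not in ("continue", "from_scratch"):
            raise ConfigValueError("retrain_mode: must be 'continue' or 'from_scratch'")
        if self.initial_epochs is not None and self.initial_epochs < 0:
            raise ConfigValueError("initial_epochs: must be >= 0")


@dataclass
class RoundRecord:
    """Bookkeeping for one self-training round."""

    round_index: int
    num_pseudo_added: int
    mean_train_loss: float
    held_out_metrics: Optional[MetricReport] = None


def partition_unlabeled(
    unlabeled: list[Volume], k: int, seed: int = 0
) -> list[list[Volume]]:
    """Random disjoint subsets covering the input, sizes differing by <= 1."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not unlabeled:
        raise ValueError("unlabeled list is empty")
    if k > len(unlabeled):
        raise ValueError(f"cannot split {len(unlabeled)} volumes into {k} subsets")
    order = np.random.default_rng(seed).permutation(len(unlabeled))
    base, extra = divmod(len(unlabeled), k)
    subsets: list[list[Volume]] = []
    start = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        subsets.append([unlabeled[j] for j in order[start:start + size]])
        start += size
    return subsets


def pseudo_label(
    net: SegmentationNetwork,
    subset: list[Volume],
    use_crf: bool = True,
    crf: CrfConfig | None = None,
    min_confidence: float | None = None,
) -> list[LabeledPair]:
    """Predict each volume and return pseudo-labeled pairs.

    With ``use_crf`` the softmax output is refined by mean-field CRF
    inference before the argmax; otherwise the argmax is taken
    directly. ``min_confidence``, when set, drops volumes whose mean
    per-voxel winning probability falls below the threshold; the
    default (None) keeps every prediction.
    """
    crf = crf if crf is not None else CrfConfig()
    out = []
    for vol in subset:
        pm = net.predict(vol)
        if use_crf:
            refined, labels = mean_field_refine(pm, vol, crf)
            conf_probs = refined.probs
        else:
            labels = pm.argmax_labels()
            conf_probs = pm.probs
        if min_confidence is not None:
            confidence = float(conf_probs.max(axis=0).mean())
            if confidence < min_confidence:
                continue
        out.append(LabeledPair(vol, labels, source=PSEUDO_LABEL))
    return out


def extend_training_set(
    current: list[LabeledPair], pseudo: list[LabeledPair]
) -> list[LabeledPair]:
    """Concatenate; a pseudo pair may never shadow a true-labeled id."""
    true_ids = {p.volume.id for p in current if p.source == TRUE_LABEL}
    for p in pseudo:
        if p.volume.id in true_ids:
            raise IdCollisionError(
                f"pseudo-labeled volume {p.volume.id!r} collides with a true-labeled pair"
            )
    return list(current) + list(pseudo)


def _mean_held_out(net: SegmentationNetwork, held_out: list[LabeledPair]) -> MetricReport:
    """Average foreground-pooled metrics over the held-out pairs."""
    dices, assds, hds = [], [], []
    unit = "voxel"
    for pair in held_out:
        pred = net.predict(pair.volume).argmax_labels()
        pred.num_classes = pair.labels.num_classes
        rep = evaluate(pred, pair.labels, spacing=pair.volume.spacing)
        unit = rep.unit
        if rep.dice is not None:
            dices.append(rep.dice)
            assds.append(rep.assd)
            hds.append(rep.hd95)
    if not dices:
        return MetricReport(dice=None, assd=None, hd95=None, unit=unit)
    return MetricReport(
        dice=float(np.mean(dices)),
        assd=float(np.mean(assds)),
        hd95=float(np.mean(hds)),
        unit=unit,
    )


def run_self_training(
    cfg: SelfTrainingConfig,
    data: DatasetSplit,
    held_out: list[LabeledPair] | None = None,
    on_round=None,
) -> tuple[SegmentationNetwork, list[RoundRecord]]:
    """The full loop; returns the final network and one record per round.

    ``on_round(round_index, pseudo_pairs)``, when given, is called with
    each round's freshly generated pseudo-labeled pairs (used e.g. to
    write them to disk).
    """
    if not data.labeled:
        raise ValueError("labeled set is empty")
    net = build_network(cfg.network)
    init_epochs = cfg.initial_epochs if cfg.initial_epochs is not None else cfg.train.epochs
    base_train = replace(cfg.train, epochs=init_epochs, seed=cfg.seed)
    net, history = train_supervised(net, list(data.labeled), base_train)
    records: list[RoundRecord] = []
    if cfg.rounds == 0 or not data.unlabeled:
        return net, records
    subsets = partition_unlabeled(data.unlabeled, cfg.num_subsets, seed=cfg.seed)
    current: list[LabeledPair] = list(data.labeled)
    for r in range(cfg.rounds):
        pseudo = pseudo_label(net, subsets[r], cfg.use_crf, cfg.crf,
                              min_confidence=cfg.min_confidence)
        if on_round is not None:
            on_round(r + 1, pseudo)
        current = extend_training_set(current, pseudo)
        if cfg.retrain_mode == "from_scratch":
            net = build_network(cfg.network)
        round_train = replace(cfg.train, seed=cfg.seed + r + 1)
        net, history = train_supervised(net, current, round_train)
        rec = RoundRecord(
            round_index=r + 1,
            num_pseudo_added=len(pseudo),
            mean_train_loss=float(np.mean(history)) if history else float("nan"),
            held_out_metrics=_mean_held_out(net, held_out) if held_out else None,
        )
        records.append(rec)
    return net, records
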