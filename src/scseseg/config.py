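"""Strict configuration loading.

A run is configured by a flat YAML document with one section per
module (``network``, ``train``, ``crf``, ``selftrain``, ``phantom``,
``paths``, ``log_level``). Unspecified keys take the documented
defaults — the published training settings where such exist (learning
rate 0.0001, 150 epochs, batch size 1, Adam, 5 unlabeled subsets, 5
CRF iterations). Unknown keys are an error, never a warning; invalid
values raise an error naming the offending field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .crf import CrfConfig
from .errors import ConfigParseError, ConfigValueError, UnknownConfigKeyError
from .network import NetworkConfig, TrainConfig
from .phantom import PhantomConfig
from .selftrain import SelfTrainingConfig


@dataclass
class RunConfig:
    """Validated, fully-defaulted configuration for every command."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    crf: CrfConfig = field(default_factory=CrfConfig)
    selftrain: SelfTrainingConfig = field(default_factory=SelfTrainingConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    paths: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # the loop reuses the same sub-configs the other commands see
        self.selftrain.network = self.network
        self.selftrain.train = self.train
        self.selftrain.crf = self.crf


_SECTIONS = {
    "network": NetworkConfig,
    "train": TrainConfig,
    "crf": CrfConfig,
    "selftrain": SelfTrainingConfig,
    "phantom": PhantomConfig,
}
# keys of SelfTrainingConfig that belong in the YAML (its sub-configs
# come from their own sections)
_SELFTRAIN_OWN = {
    "num_subsets", "rounds", "initial_epochs", "retrain_mode",
    "use_crf", "min_confidence", "seed",
}


def _build_section(name: str, cls, payload: dict):
    allowed = {f.name for f in dataclasses.fields(cls)}
    if name == "selftrain":
        allowed = _SELFTRAIN_OWN
    unknown = set(payload) - allowed
    if unknown:
        raise UnknownConfigKeyError(
            f"unknown key(s) in section {name!r}: {', '.join(sorted(unknown))}"
        )
    try:
        return cls(**payload)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigValueError):
            raise
        raise ConfigValueError(f"section {name!r}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML config file into a :class:`RunConfig`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config file: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigParseError(f"could not parse {path}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigParseError(f"{path} must hold a mapping at the top level")
    known_top = set(_SECTIONS) | {"paths", "log_level"}
    unknown = set(doc) - known_top
    if unknown:
        raise UnknownConfigKeyError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        payload = doc.get(name, {}) or {}
        if not isinstance(payload, dict):
            raise ConfigParseError(f"section {name!r} must be a mapping")
        kwargs[name] = _build_section(name, cls, payload)
    paths = doc.get("paths", {}) or {}
    if not isinstance(paths, dict):
        raise ConfigParseError("section 'paths' must be a mapping")
    return RunConfig(paths=paths, log_level=str(doc.get("log_level", "INFO")), **kwargs)
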