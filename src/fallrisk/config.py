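"""YAML pipeline configuration with strict validation.

One file configures every stage; unknown keys anywhere are rejected so
typos fail loudly.  Every hyperparameter of the training search space is
exposed under ``model`` and ``train``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .augment import AugmentConfig
from .errors import ConfigurationError
from .model import ModelConfig
from .synthetic import DEFAULT_ACTIVITIES, SimulationConfig
from .train import TrainConfig


@dataclass
class PreprocessSection:
    window_s: float = 10.0
    overlap_s: float = 1.25
    train_fraction: float = 0.2
    normalize: str = "zscore"


@dataclass
class DetectSection:
    weight_threshold: float = 0.1
    accel_threshold: float = 5.0
    jump_level: float = 15.0
    jump_window_ms: float = 300.0
    refractory_ms: float = 250.0
    projection: str = "column"


@dataclass
class EvaluateSection:
    modes: tuple = ("before", "after", "centered")
    windows_ms: tuple = (125.0, 250.0, 500.0)


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    detect: DetectSection = field(default_factory=DetectSection)
    evaluate: EvaluateSection = field(default_factory=EvaluateSection)


_SECTION_TYPES = {
    "simulate": SimulationConfig,
    "preprocess": PreprocessSection,
    "augment": AugmentConfig,
    "model": ModelConfig,
    "train": TrainConfig,
    "detect": DetectSection,
    "evaluate": EvaluateSection,
}


def _build_section(name: str, cls, payload: dict):
    if not isinstance(payload, dict):
        raise ConfigurationError(f"section {name!r} must be a mapping")
    allowed = {f.name for f in fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in section {name!r}; "
            f"allowed: {sorted(allowed)}")
    kwargs = dict(payload)
    if name == "simulate" and "activities" in kwargs:
        kwargs["activities"] = tuple(
            (str(a[0]), float(a[1]), float(a[2])) for a in kwargs["activities"])
    if name == "evaluate":
        for key in ("modes", "windows_ms"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
    if name == "train" and "augment" in kwargs:
        kwargs["augment"] = _build_section("train.augment", AugmentConfig,
                                           kwargs["augment"])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"section {name!r}: {exc}") from exc


def load_config(path) -> PipelineConfig:
    """Load and validate a pipeline YAML file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    payload = yaml.safe_load(path.read_text()) or {}
    if not isinstance(payload, dict):
        raise ConfigurationError("top-level config must be a mapping")
    unknown = set(payload) - set(_SECTION_TYPES) - {"seed"}
    if unknown:
        raise ConfigurationError(
            f"unknown top-level key(s) {sorted(unknown)}; "
            f"allowed: {sorted(set(_SECTION_TYPES) | {'seed'})}")
    cfg = PipelineConfig()
    if "seed" in payload:
        cfg.seed = int(payload["seed"])
    for name, cls in _SECTION_TYPES.items():
        if name in payload:
            setattr(cfg, name, _build_section(name, cls, payload[name]))
    # propagate the global seed into sections that carry one
    cfg.simulate.seed = payload.get("simulate", {}).get("seed", cfg.seed)
    cfg.model.seed = payload.get("model", {}).get("seed", cfg.seed)
    cfg.train.seed = payload.get("train", {}).get("seed", cfg.seed)
    return cfg
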