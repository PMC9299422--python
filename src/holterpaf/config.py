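"""One YAML config governing every pipeline stage.

The constants the method fixes (7-s segments, 128 Hz, STFT window 50,
+/-3.5-s excision, 22:00-07:00 nighttime, k = 5 folds, 1,000 bootstraps)
live here as defaults in one auditable place; CLI flags override the file.
Unknown keys are rejected with an explicit listing, and a config round-trips
through YAML losslessly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import SimConfig

__all__ = [
    "PreprocessSection", "EncoderSection", "PatientSection", "EvalSection",
    "RunConfig", "load_config", "save_config",
]


@dataclass
class PreprocessSection:
    setting: int = 1
    stft_window: int = 50
    stft_hop: int = 25
    noise_gate: bool = True

    def __post_init__(self):
        if self.setting not in (1, 2):
            raise ValueError("setting must be 1 (with SVE) or 2 (without)")
        if self.stft_window < 2 or self.stft_hop < 1:
            raise ValueError("invalid STFT geometry")


@dataclass
class EncoderSection:
    n_blocks: int = 3
    channels: list[int] = field(default_factory=lambda: [16, 32, 64])
    kernel_size: int = 3
    latent_dim: int = 32
    learning_rate: float = 1e-4
    batch_size: int = 1024
    max_epochs: int = 30
    patience: int = 5
    class_weight: str | None = None

    def estimator_params(self) -> dict:
        return {
            "n_blocks": self.n_blocks,
            "channels": tuple(self.channels),
            "kernel_size": self.kernel_size,
            "latent_dim": self.latent_dim,
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "max_epochs": self.max_epochs,
            "patience": self.patience,
            "class_weight": self.class_weight,
        }


@dataclass
class PatientSection:
    n_bins: int = 24
    n_estimators: int = 200
    learning_rate: float = 0.05
    num_leaves: int = 15
    min_child_samples: int = 3
    colsample_bytree: float = 0.9
    n_search: int = 0

    def estimator_params(self) -> dict:
        return {
            "n_estimators": self.n_estimators,
            "learning_rate": self.learning_rate,
            "num_leaves": self.num_leaves,
            "min_child_samples": self.min_child_samples,
            "colsample_bytree": self.colsample_bytree,
            "n_search": self.n_search,
        }


@dataclass
class EvalSection:
    k_folds: int = 5
    n_boot: int = 1000
    t_list: list[int] = field(default_factory=lambda: [3, 6, 12, 36])
    max_train_segments: int = 2500
    diurnal: bool = False


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    encoder: EncoderSection = field(default_factory=EncoderSection)
    patient: PatientSection = field(default_factory=PatientSection)
    eval: EvalSection = field(default_factory=EvalSection)
    seed: int = 0


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - names)
    if unknown:
        raise ValueError(f"unknown config keys under '{path}': {unknown}")
    return cls(**data)


_SECTIONS = {
    "sim": SimConfig,
    "preprocess": PreprocessSection,
    "encoder": EncoderSection,
    "patient": PatientSection,
    "eval": EvalSection,
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are an error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = sorted(set(raw) - set(_SECTIONS) - {"seed"})
    if unknown:
        raise ValueError(f"unknown top-level config keys: {unknown}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {}) or {}
        if not isinstance(section, dict):
            raise ValueError(f"config section '{name}' must be a mapping")
        kwargs[name] = _build(cls, section, name)
    return RunConfig(seed=int(raw.get("seed", 0)), **kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
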