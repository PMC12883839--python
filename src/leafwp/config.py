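"""Experiment configuration: a strict YAML schema binding all module configs.

One YAML file holds a section per component plus a global seed; unknown keys
are rejected with the offending key path, so typos fail before any
computation. The global seed expands deterministically into per-component
seeds: each repetition uses a split seed (seed + repetition index), and the
GAN, model-init and data-loader generators are derived inside the training
routine as ``component_base + split_seed + fixed offset`` — so any single
repetition can be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .cgan_augment import CGANConfig
from .darn_regression import LossConfig
from .eval_protocol import TrainConfig
from .irac_features import IRACConfig
from .synthetic_data import SimulationConfig

__all__ = ["ExperimentConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Schema violation, reported with the offending key path."""


@dataclass
class EvalSection:
    n_repetitions: int = 10
    grid_l: float = 0.15


@dataclass
class DataSection:
    path: str | None = None
    unit: str = "MPa"


@dataclass
class ExperimentConfig:
    seed: int = 0
    output_dir: str = "runs"
    data: DataSection = field(default_factory=DataSection)
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    cgan: CGANConfig = field(default_factory=CGANConfig)
    irac: IRACConfig = field(default_factory=IRACConfig)
    darn: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalSection = field(default_factory=EvalSection)

    def split_seeds(self) -> list[int]:
        return [self.seed + i for i in range(self.eval.n_repetitions)]


_SECTION_TYPES = {
    "data": DataSection,
    "simulate": SimulationConfig,
    "cgan": CGANConfig,
    "irac": IRACConfig,
    "darn": LossConfig,
    "train": TrainConfig,
    "eval": EvalSection,
}

#: keys that must be spelled out when their section is present — the core
#: hyperparameters an experiment report must state.
_REQUIRED_IN_SECTION = {"darn": ("sigma", "C")}

_TUPLE_FIELDS = {"kernel_sizes", "acmix_branches", "gen_hidden", "disc_hidden", "psi_range_mpa"}


def _build_section(name: str, cls, raw: dict):
    valid = {f.name for f in fields(cls)}
    for key in raw:
        if key not in valid:
            raise ConfigError(f"unknown key '{name}.{key}'")
    for req in _REQUIRED_IN_SECTION.get(name, ()):
        if req not in raw:
            raise ConfigError(f"missing required key '{name}.{req}'")
    coerced = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
        for k, v in raw.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{name}': {exc}") from exc


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate an experiment YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")
    top_valid = {"seed", "output_dir"} | set(_SECTION_TYPES)
    for key in raw:
        if key not in top_valid:
            raise ConfigError(f"unknown key '{key}'")
    kwargs: dict = {}
    if "seed" in raw:
        if not isinstance(raw["seed"], int):
            raise ConfigError("'seed' must be an integer")
        kwargs["seed"] = raw["seed"]
    if "output_dir" in raw:
        kwargs["output_dir"] = str(raw["output_dir"])
    for name, cls in _SECTION_TYPES.items():
        if name in raw:
            section = raw[name]
            if not isinstance(section, dict):
                raise ConfigError(f"section '{name}' must be a mapping")
            kwargs[name] = _build_section(name, cls, section)
    return ExperimentConfig(**kwargs)
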