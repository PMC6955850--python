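"""Run configuration: one serializable object covering the whole pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .design_space import DEFAULT_BOUNDS, DesignSpace
from .exceptions import ConfigError
from .synthetic_fea import SyntheticConfig
from .training import TrainConfig

CONFIG_VERSION = 1


@dataclass
class SamplingConfig:
    n: int = 984
    scheme: str = "latin-hypercube"
    seed: int = 0


@dataclass
class EvalConfig:
    rho: list[float] = field(default_factory=lambda: [50.0, 70.0, 90.0])
    repeats: int = 100
    seed: int = 0


@dataclass
class RunConfig:
    """Everything needed to regenerate a study: bounds, sampling, synthesis,
    training, evaluation, output directory."""

    bounds: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_BOUNDS.items()})
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    target_nodes: int = 1381
    train: TrainConfig = field(default_factory=TrainConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    outdir: str = "results"
    version: int = CONFIG_VERSION

    def design_space(self) -> DesignSpace:
        return DesignSpace({k: tuple(v) for k, v in self.bounds.items()})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"]["stress_scale"] = list(d["synthetic"]["stress_scale"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        version = d.get("version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise ConfigError(f"unsupported config version {version}")
        syn = dict(d.get("synthetic", {}))
        if "stress_scale" in syn:
            syn["stress_scale"] = tuple(syn["stress_scale"])
        if "n_modes" in syn:
            syn["n_modes"] = int(syn["n_modes"])
        return cls(
            bounds=d.get("bounds", {k: list(v) for k, v in DEFAULT_BOUNDS.items()}),
            sampling=SamplingConfig(**d.get("sampling", {})),
            synthetic=SyntheticConfig(**syn),
            target_nodes=int(d.get("target_nodes", 1381)),
            train=TrainConfig(**d.get("train", {})),
            evaluation=EvalConfig(**d.get("evaluation", {})),
            outdir=d.get("outdir", "results"),
            version=version,
        )


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} is not a mapping")
    return RunConfig.from_dict(data)
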