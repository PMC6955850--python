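"""Training routines: three-phase ML-model-a and single-phase ML-model-d.

Phases for the autoencoder-based model, mirroring its construction:

1. unsupervised autoencoder training on the (standardized) training fields;
2. supervised training of the small mapping net on the encoder's codes;
3. end-to-end fine-tuning of mapping + copied decoder on the fields.

Both model families minimize plain MSE with Adamax at its default
hyperparameters; all three stress components enter one loss with equal weight.
Every routine is reproducible bit-for-bit under a fixed seed on a single CPU
thread.  Epoch counts default to single-CPU desk scale and are fully
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design_space import DesignSpace, scale_to_unit
from .nn import MLP, Adamax, fit, mse
from .surrogate_models import (
    Autoencoder,
    SurrogateModel,
    assemble_model_a,
    build_direct_net,
    build_mapping_net,
    instantiate,
)


@dataclass
class TrainConfig:
    """Optimizer, loss and schedule settings shared by both model families."""

    optimizer: str = "adamax"
    optimizer_params: dict = field(
        default_factory=lambda: {"lr": 0.002, "beta1": 0.9, "beta2": 0.999, "eps": 1e-7}
    )
    loss: str = "mse"
    ae_epochs: int = 150
    map_epochs: int = 4000
    finetune_epochs: int = 80
    direct_epochs: int = 400
    batch_size: int | None = 32
    seed: int = 0
    patience: int | None = None  # reserved; no early stopping by default
    lr_decay: float = 1.0  # one-step lr multiplier applied at 80% of each phase
    code_dim: int = 8
    encoder_hidden: int = 512
    code_normalization: str = "l2"

    def __post_init__(self) -> None:
        for name in ("ae_epochs", "map_epochs", "finetune_epochs", "direct_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def make_optimizer(self) -> Adamax:
        if self.optimizer != "adamax":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        return Adamax(**self.optimizer_params)

    def manifest(self) -> dict:
        return {
            "optimizer": self.optimizer,
            "optimizer_params": dict(self.optimizer_params),
            "loss": self.loss,
            "epochs": {
                "autoencoder": self.ae_epochs,
                "mapping": self.map_epochs,
                "finetune": self.finetune_epochs,
                "direct": self.direct_epochs,
            },
            "batch_size": self.batch_size,
            "lr_decay": self.lr_decay,
            "seed": self.seed,
        }


def standardize_fields(fields: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature standardization; constant features get unit scale."""
    mean = fields.mean(axis=0)
    sd = fields.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    return (fields - mean) / sd, mean, sd


def train_autoencoder(
    fields: np.ndarray, cfg: TrainConfig | None = None
) -> tuple[Autoencoder, list[float]]:
    """Unsupervised phase: minimize MSE(field, decode(encode(field)))."""
    cfg = cfg or TrainConfig()
    if fields.shape[0] < 2:
        raise ValueError("autoencoder training needs at least 2 samples")
    ae = Autoencoder(
        field_dim=fields.shape[1],
        code_dim=cfg.code_dim,
        encoder_hidden=cfg.encoder_hidden,
        normalization=cfg.code_normalization,
        seed=cfg.seed,
    )
    history = fit(
        ae.net,
        fields,
        fields,
        epochs=cfg.ae_epochs,
        batch_size=cfg.batch_size,
        seed=cfg.seed,
        optimizer=cfg.make_optimizer(),
        lr_decay=cfg.lr_decay,
    )
    return ae, history


def train_mapping(
    designs01: np.ndarray, codes: np.ndarray, cfg: TrainConfig | None = None
) -> tuple[MLP, list[float]]:
    """Supervised phase: fit the small net design -> code on encoder outputs."""
    cfg = cfg or TrainConfig()
    net = instantiate(build_mapping_net(codes.shape[1]), seed=cfg.seed + 10)
    history = fit(
        net,
        designs01,
        codes,
        epochs=cfg.map_epochs,
        batch_size=cfg.batch_size,
        seed=cfg.seed + 10,
        optimizer=cfg.make_optimizer(),
        lr_decay=cfg.lr_decay,
    )
    return net, history


def finetune_model_a(
    model: SurrogateModel,
    designs01: np.ndarray,
    fields: np.ndarray,
    cfg: TrainConfig | None = None,
) -> list[float]:
    """End-to-end phase on the composite net (in place).

    The training-set MSE after this phase never exceeds the assembled model's:
    if the last optimizer state is worse than the warm start, the warm-start
    weights are restored.
    """
    cfg = cfg or TrainConfig()
    before = mse(model.net.forward(designs01), fields)
    snapshot = model.net.get_weights()
    history = fit(
        model.net,
        designs01,
        fields,
        epochs=cfg.finetune_epochs,
        batch_size=cfg.batch_size,
        seed=cfg.seed + 20,
        optimizer=cfg.make_optimizer(),
        lr_decay=cfg.lr_decay,
    )
    after = mse(model.net.forward(designs01), fields)
    if after > before:
        model.net.set_weights(snapshot)
        history = history + [before]
    return history


def train_direct(
    designs01: np.ndarray, fields: np.ndarray, cfg: TrainConfig | None = None
) -> tuple[MLP, list[float]]:
    """Single-phase supervised training of the direct feedforward net."""
    cfg = cfg or TrainConfig()
    if fields.shape[0] < 2:
        raise ValueError("direct training needs at least 2 samples")
    net = instantiate(build_direct_net(fields.shape[1]), seed=cfg.seed + 30)
    history = fit(
        net,
        designs01,
        fields,
        epochs=cfg.direct_epochs,
        batch_size=cfg.batch_size,
        seed=cfg.seed + 30,
        optimizer=cfg.make_optimizer(),
        lr_decay=cfg.lr_decay,
    )
    return net, history


def fit_model_a(
    design_array: np.ndarray,
    fields: np.ndarray,
    kind: str,
    cfg: TrainConfig | None = None,
    space: DesignSpace | None = None,
) -> SurrogateModel:
    """Full three-phase pipeline returning a trained autoencoder-based model."""
    cfg = cfg or TrainConfig()
    space = space or DesignSpace.default()
    x01 = scale_to_unit(design_array, space)
    y, y_mean, y_std = standardize_fields(fields)

    ae, ae_hist = train_autoencoder(y, cfg)
    codes = ae.encode(y)
    mapping, map_hist = train_mapping(x01, codes, cfg)
    model = assemble_model_a(mapping, ae.decoder_layers, kind=kind, space=space)
    ft_hist = finetune_model_a(model, x01, y, cfg)

    model.y_mean, model.y_std = y_mean, y_std
    model.manifest = {
        "kind": kind,
        "train": cfg.manifest(),
        "loss_final": {
            "autoencoder": ae_hist[-1],
            "mapping": map_hist[-1],
            "finetune": ft_hist[-1],
        },
    }
    return model


def fit_model_d(
    design_array: np.ndarray,
    fields: np.ndarray,
    kind: str,
    cfg: TrainConfig | None = None,
    space: DesignSpace | None = None,
) -> SurrogateModel:
    """Single-phase pipeline returning a trained direct model."""
    cfg = cfg or TrainConfig()
    space = space or DesignSpace.default()
    x01 = scale_to_unit(design_array, space)
    y, y_mean, y_std = standardize_fields(fields)
    net, hist = train_direct(x01, y, cfg)
    return SurrogateModel(
        kind=kind,
        net=net,
        space=space,
        y_mean=y_mean,
        y_std=y_std,
        manifest={"kind": kind, "train": cfg.manifest(), "loss_final": {"direct": hist[-1]}},
    )
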