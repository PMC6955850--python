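"""The two surrogate network families for leaflet shape and stress fields.

*ML-model-a* (autoencoder-based): a small mapping net takes the three design
parameters to an 8-number *field code*, and a decoder expands the code to the
full nodal field (4143 numbers for the default 1381-node mesh).  The decoder is
obtained by unsupervised autoencoder training on the fields, copied into the
composite model, and later fine-tuned end-to-end.

*ML-model-d* (direct): one feedforward net from the design parameters straight
to the field, hidden widths 32-64-256, all Softplus, linear output.

Design parameters are min-max scaled to [0, 1] with the design-space bounds;
output fields are standardized per feature with training-set statistics stored
on the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design_space import DesignParams, DesignSpace, scale_to_unit
from .exceptions import ConfigError, StateError
from .nn import MLP, Dense, L2Normalize, Standardize

MODEL_KINDS = ("model_a_shape", "model_a_stress", "model_d_shape", "model_d_stress")


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered (width, activation) layer list with explicit input dimension."""

    layer_sizes: tuple[tuple[int, str], ...]
    input_dim: int

    def __post_init__(self) -> None:
        for width, act in self.layer_sizes:
            if width <= 0:
                raise ConfigError("layer widths must be positive")
            if act not in ("softplus", "linear", "normalization"):
                raise ConfigError(f"unknown activation {act!r}")

    @property
    def output_dim(self) -> int:
        return self.layer_sizes[-1][0]


def build_mapping_net(code_dim: int = 8) -> NetworkSpec:
    """Design parameters -> field code: 3 -> 16 -> 16 -> code_dim."""
    return NetworkSpec(
        layer_sizes=((16, "softplus"), (16, "softplus"), (code_dim, "linear")),
        input_dim=3,
    )


def build_decoder(field_dim: int = 4143, code_dim: int = 8) -> NetworkSpec:
    """Field code -> nodal field: code_dim -> 512 -> field_dim."""
    return NetworkSpec(
        layer_sizes=((512, "softplus"), (field_dim, "linear")),
        input_dim=code_dim,
    )


def build_encoder(
    field_dim: int, code_dim: int = 8, hidden: int = 512, normalization: str = "l2"
) -> NetworkSpec:
    """Nodal field -> field code: Softplus hidden, linear code, normalization.

    The hidden width is not pinned by the architecture description; the default
    mirrors the decoder (512).  ``normalization`` is 'l2' (per-sample unit
    Euclidean length, the default) or 'standardize' (per-code training-batch
    statistics).
    """
    if normalization not in ("l2", "standardize"):
        raise ConfigError(f"unknown code normalization {normalization!r}")
    return NetworkSpec(
        layer_sizes=(
            (hidden, "softplus"),
            (code_dim, "linear"),
            (code_dim, "normalization"),
        ),
        input_dim=field_dim,
    )


def build_autoencoder_spec(
    field_dim: int, code_dim: int = 8, encoder_hidden: int = 512
) -> tuple[NetworkSpec, NetworkSpec]:
    return (
        build_encoder(field_dim, code_dim, encoder_hidden),
        build_decoder(field_dim, code_dim),
    )


def build_direct_net(field_dim: int = 4143) -> NetworkSpec:
    """Design parameters -> nodal field: 3 -> 32 -> 64 -> 256 -> field_dim."""
    return NetworkSpec(
        layer_sizes=(
            (32, "softplus"),
            (64, "softplus"),
            (256, "softplus"),
            (field_dim, "linear"),
        ),
        input_dim=3,
    )


def instantiate(spec: NetworkSpec, seed: int = 0, normalization: str = "l2") -> MLP:
    """Build an MLP with seeded Glorot-uniform weights from a NetworkSpec."""
    rng = np.random.default_rng(seed)
    layers: list = []
    n_in = spec.input_dim
    for width, act in spec.layer_sizes:
        if act == "normalization":
            layers.append(L2Normalize() if normalization == "l2" else Standardize(width))
        else:
            layers.append(Dense(n_in, width, act, rng))
            n_in = width
    return MLP(layers)


class Autoencoder:
    """Field autoencoder: encode to an 8-number code, decode back to the field."""

    def __init__(
        self,
        field_dim: int,
        code_dim: int = 8,
        encoder_hidden: int = 512,
        normalization: str = "l2",
        seed: int = 0,
    ):
        enc_spec, dec_spec = build_autoencoder_spec(field_dim, code_dim, encoder_hidden)
        encoder = instantiate(enc_spec, seed=seed, normalization=normalization)
        decoder = instantiate(dec_spec, seed=seed + 1)
        self.field_dim = field_dim
        self.code_dim = code_dim
        self.normalization = normalization
        self.net = MLP(encoder.layers + decoder.layers)
        self._split = len(encoder.layers)

    @property
    def encoder_layers(self):
        return self.net.layers[: self._split]

    @property
    def decoder_layers(self):
        return self.net.layers[self._split :]

    def encode(self, fields: np.ndarray) -> np.ndarray:
        return self.net.forward(np.atleast_2d(fields), stop=self._split)

    def decode(self, codes: np.ndarray) -> np.ndarray:
        return self.net.forward_from(np.atleast_2d(codes), self._split)

    def reconstruct(self, fields: np.ndarray) -> np.ndarray:
        return self.net.forward(np.atleast_2d(fields))


@dataclass
class SurrogateModel:
    """A trained design-to-field regressor with its standardization constants."""

    kind: str
    net: MLP
    space: DesignSpace
    y_mean: np.ndarray | None = None
    y_std: np.ndarray | None = None
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ConfigError(f"unknown model kind {self.kind!r}")

    @property
    def trained(self) -> bool:
        return self.y_mean is not None and self.y_std is not None

    def predict(self, designs) -> np.ndarray:
        """De-standardized flattened field(s) of length 3N per design.

        Accepts a single DesignParams (returns 1-D) or an (n, 3) array
        (returns (n, 3N)); batch prediction equals concatenated per-design
        prediction.
        """
        if not self.trained:
            raise StateError("model has no standardization constants; train it first")
        single = isinstance(designs, DesignParams)
        arr = designs.as_array()[None, :] if single else np.atleast_2d(np.asarray(designs))
        x = scale_to_unit(arr, self.space)
        out = self.net.forward(x) * self.y_std + self.y_mean
        return out[0] if single else out


def assemble_model_a(
    mapping: MLP, decoder_layers: list, kind: str, space: DesignSpace | None = None
) -> SurrogateModel:
    """Compose a trained mapping net with a *copy* of trained decoder layers.

    Before fine-tuning the composite output equals decode(mapping(x)) exactly;
    fine-tuning may subsequently change the copied weights.
    """
    import copy as _copy

    mapping_out = mapping.layers[-1].W.shape[1]
    decoder_in = decoder_layers[0].W.shape[0]
    if mapping_out != decoder_in:
        raise ConfigError(
            f"mapping output dim {mapping_out} != decoder input dim {decoder_in}"
        )
    composite = MLP(mapping.layers + [_copy.deepcopy(l) for l in decoder_layers])
    return SurrogateModel(kind=kind, net=composite, space=space or DesignSpace.default())
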