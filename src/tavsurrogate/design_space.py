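"""Three-parameter design space for transcatheter aortic valve (TAV) leaflets.

A TAV leaflet design is fully described by the triple ``(a, b, ssl)``:

``a``
    Attachment-curve coefficient in mm; sets the vertical position and
    steepness of the scallop-shaped attachment edge of the flat 2D leaflet.
``b``
    Dimensionless exponential shape coefficient of the stent suturing line
    (SSL) in 3D cylindrical coordinates.
``ssl``
    Length of the stent suturing line in mm.  The same length is enforced for
    the 2D attachment edge and the 3D suturing curve, which couples the flat
    leaflet blank to the mounted 3D shape.

The feasible ranges used throughout the package are a in [4.57, 6.35] mm,
b in [3.0, 3.4] and SSL in [18.4, 20.1] mm.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import qmc

from .exceptions import ConfigError

PARAM_NAMES: tuple[str, ...] = ("a", "b", "ssl")

#: Feasible parameter ranges (closed intervals).
DEFAULT_BOUNDS: Mapping[str, tuple[float, float]] = MappingProxyType(
    {"a": (4.57, 6.35), "b": (3.0, 3.4), "ssl": (18.4, 20.1)}
)

SAMPLING_SCHEMES = ("grid", "latin-hypercube", "uniform-random")


@dataclass(frozen=True)
class DesignParams:
    """One leaflet design: ``a`` [mm], ``b`` [-], ``ssl`` [mm]."""

    a: float
    b: float
    ssl: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.ssl], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "DesignParams":
        a, b, ssl = (float(v) for v in arr)
        return cls(a, b, ssl)


@dataclass(frozen=True, eq=False)
class DesignSpace:
    """Axis-aligned box of feasible designs; every interval must be non-degenerate."""

    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if name not in self.bounds:
                raise ConfigError(f"missing bounds for parameter {name!r}")
            lo, hi = self.bounds[name]
            if not (math.isfinite(lo) and math.isfinite(hi)):
                raise ConfigError(f"non-finite bounds for parameter {name!r}")
            if not lo < hi:
                raise ConfigError(
                    f"degenerate bounds for parameter {name!r}: min must be < max"
                )
        object.__setattr__(self, "bounds", MappingProxyType(dict(self.bounds)))

    @classmethod
    def default(cls) -> "DesignSpace":
        return cls(DEFAULT_BOUNDS)

    @property
    def n_params(self) -> int:
        return len(PARAM_NAMES)

    def lows(self) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in PARAM_NAMES])

    def highs(self) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in PARAM_NAMES])


def validate_params(p: DesignParams, space: DesignSpace | None = None) -> bool:
    """Return True iff every parameter lies within its closed bound.

    Raises ``ConfigError`` for non-finite parameter values.
    """
    space = space or DesignSpace.default()
    values = p.as_array()
    if not np.all(np.isfinite(values)):
        raise ConfigError(f"non-finite design parameters: {p}")
    lo, hi = space.lows(), space.highs()
    return bool(np.all(values >= lo) and np.all(values <= hi))


def extreme_designs(space: DesignSpace | None = None) -> list[DesignParams]:
    """The 2^k corner designs of the bounds hypercube (8 for the default space)."""
    space = space or DesignSpace.default()
    corners = itertools.product(*(space.bounds[n] for n in PARAM_NAMES))
    return [DesignParams(*c) for c in corners]


def scale_to_unit(designs: np.ndarray, space: DesignSpace | None = None) -> np.ndarray:
    """Min-max scale an (n, 3) design array into [0, 1]^3 using the space bounds."""
    space = space or DesignSpace.default()
    lo, hi = space.lows(), space.highs()
    return (np.asarray(designs, dtype=float) - lo) / (hi - lo)


def sample_designs(
    space: DesignSpace | None = None,
    n: int = 1,
    scheme: str = "latin-hypercube",
    seed: int = 0,
) -> list[DesignParams]:
    """Draw ``n`` designs from the space with a reproducible, seeded scheme.

    Schemes
    -------
    ``latin-hypercube``
        Space-filling stratified sample (scipy QMC engine).
    ``uniform-random``
        I.i.d. uniform draws.
    ``grid``
        Full tensor grid; ``n`` must be a perfect cube ``k**3`` and the grid
        has ``k`` equispaced levels per axis (a single level sits at the
        interval midpoint).
    """
    space = space or DesignSpace.default()
    if n < 1:
        raise ConfigError("n must be >= 1")
    lo, hi = space.lows(), space.highs()
    if scheme == "latin-hypercube":
        engine = qmc.LatinHypercube(d=space.n_params, seed=seed)
        unit = engine.random(n)
    elif scheme == "uniform-random":
        rng = np.random.default_rng(seed)
        unit = rng.uniform(size=(n, space.n_params))
    elif scheme == "grid":
        k = round(n ** (1.0 / space.n_params))
        if k**space.n_params != n:
            raise ConfigError(
                f"grid scheme needs n = k^{space.n_params}; got n={n}"
            )
        if k == 1:
            levels = [np.array([0.5])] * space.n_params
        else:
            levels = [np.linspace(0.0, 1.0, k)] * space.n_params
        unit = np.array(list(itertools.product(*levels)))
    else:
        raise ConfigError(
            f"unknown sampling scheme {scheme!r}; expected one of {SAMPLING_SCHEMES}"
        )
    values = lo + unit * (hi - lo)
    return [DesignParams(*row) for row in values]


def designs_to_array(designs: Sequence[DesignParams]) -> np.ndarray:
    return np.array([d.as_array() for d in designs])
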