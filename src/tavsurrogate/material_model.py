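"""Fiber-reinforced hyperelastic strain energy for pericardial leaflet tissue.

The energy is an exponential-isotropic variant of the Gasser-Ogden-Holzapfel
(GOH) model with two symmetric fiber families:

    W = C10 * (exp(C01 * (I1b - 3)) - 1)
        + k1 / (2 k2) * sum_i (exp(k2 * (I4b_i - 1)^2) - 1)
        + (1 / D) * (J - 1)^2

where ``I1b`` is the deviatoric first invariant, ``I4b_i`` the deviatoric
fourth invariant of fiber family i, and ``J`` the volume ratio.  The default
parameters come from planar biaxial testing of glutaraldehyde-treated porcine
pericardium.  Energies are interpreted in kPa (consistent with leaflet stresses
reported in kPa).

The default evaluation uses the fourth invariants directly in the fiber term.
The classical GOH dispersion blend ``E_i = kappa*(I1b-3) + (1-3*kappa)*(I4b_i-1)``
is available behind ``fiber_dispersion=True``; with the porcine kappa of
1.16e-7 the two variants are numerically indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, InvalidDeformationError


@dataclass(frozen=True)
class MaterialParams:
    """GOH-variant parameters; C10, k1 and W share one stress-like unit (kPa)."""

    C10: float
    C01: float
    k1: float
    k2: float
    D: float = 1e-4  # incompressibility penalty (not printed; near-incompressible)
    kappa: float = 0.0  # fiber dispersion
    theta_fiber: float = 0.0  # fiber angle, degrees

    def __post_init__(self) -> None:
        if not self.k2 > 0:
            raise ConfigError("k2 must be > 0")
        if not self.D > 0:
            raise ConfigError("D must be > 0")
        if not 0.0 <= self.kappa <= 1.0 / 3.0:
            raise ConfigError("kappa must lie in [0, 1/3]")


@dataclass(frozen=True)
class DeformationInvariants:
    """Deviatoric invariants (I1b, I4b pair) and volume ratio J of one state."""

    I1bar: float
    I4bar: tuple[float, float]
    J: float = 1.0


def default_porcine_params() -> MaterialParams:
    """Porcine-pericardium constants from planar biaxial testing."""
    return MaterialParams(
        C10=2.196,
        C01=13.48,
        k1=22.14,
        k2=107.27,
        D=1e-4,
        kappa=1.16e-7,
        theta_fiber=7.81,
    )


def strain_energy(
    inv: DeformationInvariants,
    mp: MaterialParams,
    fiber_dispersion: bool = False,
) -> float:
    """Strain-energy density W for one deformation state.

    Raises ``InvalidDeformationError`` for J <= 0.  W vanishes at the identity
    (I1b = 3, I4b = 1, J = 1) and is monotone increasing in I1b above 3.
    """
    if not np.isfinite(inv.J) or inv.J <= 0.0:
        raise InvalidDeformationError(f"volume ratio J must be > 0, got {inv.J}")
    iso = mp.C10 * np.expm1(mp.C01 * (inv.I1bar - 3.0))
    fiber = 0.0
    for i4 in inv.I4bar:
        if fiber_dispersion:
            e = mp.kappa * (inv.I1bar - 3.0) + (1.0 - 3.0 * mp.kappa) * (i4 - 1.0)
        else:
            e = i4 - 1.0
        fiber += np.expm1(mp.k2 * e * e)
    fiber *= mp.k1 / (2.0 * mp.k2)
    vol = (inv.J - 1.0) ** 2 / mp.D
    return float(iso + fiber + vol)
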