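"""Synthetic stand-in for the finite-element leaflet simulations.

Finite-element ground truth for this design family is not publicly available,
so this module generates stand-in fields with the same *structure*: per-design deformed nodal
coordinates (N x 3, mm) and in-plane stress components S11, S22, S12
(N x 3, kPa) on a fixed-ordering leaflet mesh, varying smoothly and
deterministically with the design parameters, with the attachment edge fixed
(zero displacement during pressurization) and mean |S11| exceeding mean |S22|
and mean |S12|.  It is explicitly *not* a mechanics solver: no contact, no
friction, no equilibrium — only structural fidelity to the data the surrogate
networks must learn.

Two regimes are provided:

* the default smooth pseudo-physics (mounting + pressure-scaled belly bulge +
  analytic stress shape functions), and
* a *low-rank mode* in which every field is an exact linear combination of 8
  fixed modes with smooth design-dependent coefficients — an oracle for which
  an 8-code autoencoder can achieve (near-)zero reconstruction error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .design_space import (
    DEFAULT_BOUNDS,
    DesignParams,
    DesignSpace,
    designs_to_array,
)
from .exceptions import GeometryError
from .leaflet_geometry import (
    LeafletMesh2D,
    SSLCurve3D,
    attachment_cumulative_arc,
    build_contour,
    build_ssl_curve,
    check_same_design,
    gauss_cumulative_arc,
    mesh_leaflet,
)

DATASET_VERSION = 1

#: Fraction by which the free-edge chord midpoint is pulled toward the valve axis.
_FREE_EDGE_PULL = 0.75
#: Belly-bulge displacement per mmHg at the reference design, mm.
_BULGE_PER_MMHG = 0.0045


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation settings.

    ``pressure`` is the transvalvular closure pressure in mmHg (120 at the
    reference diastolic load); displacements scale linearly with it.
    ``stress_scale`` are the (S11, S22, S12) magnitude coefficients in kPa,
    ordered so the S11 coefficient is largest — the circumferential component
    dominates in pressurized leaflets.  ``noise_sd`` is the relative standard
    deviation of optional multiplicative Gaussian noise (0 by default: the
    emulated FE data are smooth).  ``low_rank`` switches to the 8-mode oracle
    regime.
    """

    pressure: float = 120.0
    noise_sd: float = 0.0
    seed: int = 0
    stress_scale: tuple[float, float, float] = (500.0, 120.0, 180.0)
    low_rank: bool = False
    n_modes: int = 8

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        s11, s22, s12 = self.stress_scale
        if not (s11 > s22 and s11 > s12):
            raise ValueError("stress_scale must have the largest S11 coefficient")


@dataclass(frozen=True)
class FieldSample:
    """Ground truth for one design: deformed coordinates and nodal stresses."""

    design: DesignParams
    deformed_coords: np.ndarray  # (N, 3) mm
    stress: np.ndarray  # (N, 3) kPa: S11, S22, S12

    @property
    def n_nodes(self) -> int:
        return self.deformed_coords.shape[0]

    def flat_shape(self) -> np.ndarray:
        return self.deformed_coords.reshape(-1)

    def flat_stress(self) -> np.ndarray:
        return self.stress.reshape(-1)


def _scaled(design: DesignParams) -> tuple[float, float, float]:
    """Design parameters min-max scaled to [0, 1] by the feasible ranges."""
    (a0, a1), (b0, b1), (s0, s1) = (
        DEFAULT_BOUNDS["a"],
        DEFAULT_BOUNDS["b"],
        DEFAULT_BOUNDS["ssl"],
    )
    return (
        (design.a - a0) / (a1 - a0),
        (design.b - b0) / (b1 - b0),
        (design.ssl - s0) / (s1 - s0),
    )


def mount_leaflet(mesh: LeafletMesh2D, curve: SSLCurve3D) -> np.ndarray:
    """Place the flat leaflet on the stent: deterministic 2D -> 3D mapping.

    Attachment-edge nodes are mapped onto the SSL curve by matching normalized
    arc length (so the suturing-line length is preserved); the free edge is
    sent to the commissure-to-commissure chord pulled toward the valve axis
    (the coapted position); interior nodes blend linearly in the transverse
    parametric coordinate v.
    """
    check_same_design(mesh, curve)
    c = mesh.contour
    n_cols = mesh.n_cols
    xs = np.linspace(-c.half_width, c.half_width, n_cols + 2)

    # normalized 2D arc-length position of every column station
    cum2d = attachment_cumulative_arc(c, xs)
    s_norm = cum2d / cum2d[-1]

    # invert the 3D cumulative arc length on a dense theta grid
    thetas = np.linspace(-curve.theta_max, curve.theta_max, 4001)
    dz = lambda t: curve.p * curve.b * np.exp(curve.b * np.abs(t)) * np.sign(t)
    cum3d = gauss_cumulative_arc(lambda t: dz(t) / curve.radius, thetas) * curve.radius
    theta_k = np.interp(s_norm * cum3d[-1], cum3d, thetas)
    theta_k[0], theta_k[-1] = -curve.theta_max, curve.theta_max

    attach3d = curve.point(theta_k)  # (n_cols + 2, 3), exactly on the curve

    # free-edge targets: chord between the commissures, pulled toward the axis
    u = (xs + c.half_width) / (2.0 * c.half_width)
    c_left, c_right = attach3d[0], attach3d[-1]
    chord = (1.0 - u)[:, None] * c_left[None, :] + u[:, None] * c_right[None, :]
    pull = 1.0 - _FREE_EDGE_PULL * np.sin(np.pi * u)
    free3d = chord.copy()
    free3d[:, :2] *= pull[:, None]

    coords = np.empty((mesh.n_nodes, 3))
    coords[0] = attach3d[0]
    coords[-1] = attach3d[-1]
    n_rows = mesh.n_rows
    v = np.linspace(0.0, 1.0, n_rows)
    for i in range(1, n_cols + 1):
        ids = np.arange(1 + (i - 1) * n_rows, 1 + i * n_rows)
        coords[ids] = (1.0 - v)[:, None] * attach3d[i][None, :] + v[:, None] * free3d[i][None, :]
    return coords


def apply_pseudo_closure(
    mounted: np.ndarray, cfg: SyntheticConfig, design: DesignParams, mesh: LeafletMesh2D
) -> np.ndarray:
    """Pressure-driven belly bulge added to the mounted configuration.

    The displacement field is a smooth bump in the parametric coordinates that
    vanishes identically on the attachment edge (fixed nodes), points inward
    and downward, scales linearly with pressure and depends smoothly on the
    design parameters.
    """
    ah, bh, sh = _scaled(design)
    amp = (
        _BULGE_PER_MMHG
        * cfg.pressure
        * (1.0 + 0.35 * ah - 0.25 * bh + 0.30 * sh + 0.20 * ah * sh)
    )
    u, v = mesh.node_u, mesh.node_v
    bump = v**2 * 4.0 * u * (1.0 - u)

    r = np.hypot(mounted[:, 0], mounted[:, 1])
    direction = np.zeros_like(mounted)
    direction[:, 0] = -0.8 * mounted[:, 0] / r
    direction[:, 1] = -0.8 * mounted[:, 1] / r
    direction[:, 2] = -0.6
    return mounted + amp * bump[:, None] * direction


def synth_stress_field(
    deformed: np.ndarray,
    design: DesignParams,
    cfg: SyntheticConfig,
    mesh: LeafletMesh2D,
    sample_index: int = 0,
) -> np.ndarray:
    """Analytic nodal stress fields S11, S22, S12 (kPa).

    Bounded smooth shape functions of the parametric coordinates peak near the
    attachment edge and commissures (where pressurized leaflets concentrate
    stress); magnitudes and peak locations shift smoothly with the design.
    S12 is antisymmetric about the leaflet midline.  Optional multiplicative
    Gaussian noise is seeded per (config seed, sample index).
    """
    if deformed.shape[0] != mesh.n_nodes:
        raise GeometryError("deformed coordinates do not match the mesh node count")
    ah, bh, sh = _scaled(design)
    u, v = mesh.node_u, mesh.node_v
    s11c, s22c, s12c = cfg.stress_scale

    belly = np.exp(-(((u - 0.5) / 0.22) ** 2))
    comm_w = 0.12 + 0.05 * bh
    commissures = np.exp(-((u / comm_w) ** 2)) + np.exp(-(((1.0 - u) / comm_w) ** 2))

    g1 = (0.30 + 0.70 * (1.0 - v) ** 2) * (
        1.0 + 0.45 * belly * (0.5 + 0.5 * sh)
    ) * (1.0 + 0.35 * ah - 0.20 * bh + 0.25 * sh) + 0.35 * commissures * (1.0 - v)

    g2 = (0.25 + 2.0 * v * (1.0 - v)) * (1.0 + 0.30 * bh - 0.20 * ah) + 0.30 * np.exp(
        -(((v - 0.3) / 0.3) ** 2)
    ) * np.cos(np.pi * (u - 0.5)) ** 2 * (1.0 + 0.40 * sh)

    g3 = 0.80 * np.sin(np.pi * (2.0 * u - 1.0)) * (1.0 - v) * (
        1.0 + 0.30 * ah + 0.20 * bh - 0.25 * sh
    ) + 0.15 * np.sin(2.0 * np.pi * u) * v * (1.0 + 0.3 * bh)

    stress = np.column_stack([s11c * g1, s22c * g2, s12c * g3])
    if cfg.noise_sd > 0:
        rng = np.random.default_rng([cfg.seed, sample_index])
        stress = stress * (1.0 + cfg.noise_sd * rng.standard_normal(stress.shape))
    return stress


def _simulate_design(
    design: DesignParams, cfg: SyntheticConfig, target_nodes: int, sample_index: int
) -> tuple[FieldSample, LeafletMesh2D]:
    inner = _inner_cols(target_nodes)
    contour = build_contour(design, n_points=inner + 2)
    mesh = mesh_leaflet(contour, target_nodes)
    curve = build_ssl_curve(design.b, design.ssl)
    mounted = mount_leaflet(mesh, curve)
    deformed = apply_pseudo_closure(mounted, cfg, design, mesh)
    stress = synth_stress_field(deformed, design, cfg, mesh, sample_index)
    return FieldSample(design, deformed, stress), mesh


def _inner_cols(target_nodes: int) -> int:
    from .leaflet_geometry import _grid_factorization

    inner, _ = _grid_factorization(target_nodes)
    return inner


# ---------------------------------------------------------------------------
# low-rank oracle regime

_MODE_DIRS_SHAPE = np.array(
    [
        [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0],
        [0, 1, 1], [1, 0, 1], [1, -1, 0], [1, 1, 1],
    ],
    dtype=float,
)
_MODE_DIRS_SHAPE /= np.linalg.norm(_MODE_DIRS_SHAPE, axis=1, keepdims=True)
_MODE_DIRS_STRESS = _MODE_DIRS_SHAPE[::-1].copy()


def _mode_profiles(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Eight smooth (u, v) profiles, all vanishing on the attachment edge."""
    return np.stack(
        [
            v,
            v * np.sin(np.pi * u),
            v * np.cos(np.pi * u),
            v**2,
            4.0 * v * u * (1.0 - u),
            v * np.sin(2.0 * np.pi * u),
            v**2 * np.sin(np.pi * u),
            4.0 * v * (1.0 - v) * np.cos(2.0 * np.pi * u),
        ]
    )


def _mode_coefficients(design: DesignParams) -> np.ndarray:
    """Eight smooth, jointly independent functions of the design parameters."""
    ah, bh, sh = _scaled(design)
    ac, bc, sc = ah - 0.5, bh - 0.5, sh - 0.5
    return np.array(
        [
            ac,
            bc,
            sc,
            ac * bc,
            bc * sc,
            ac * sc,
            ac * ac - 1.0 / 12.0,
            math.sin(math.pi * sh) - 2.0 / math.pi,
        ]
    )


def _low_rank_bases(mesh: LeafletMesh2D) -> tuple[np.ndarray, np.ndarray]:
    profiles = _mode_profiles(mesh.node_u, mesh.node_v)  # (8, N)
    shape_basis = np.einsum("kn,kc->knc", profiles, _MODE_DIRS_SHAPE).reshape(8, -1)
    stress_basis = np.einsum("kn,kc->knc", profiles, _MODE_DIRS_STRESS).reshape(8, -1)
    return shape_basis, stress_basis


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class FieldDataset:
    """Aligned arrays for a whole synthetic study plus the shared mesh."""

    designs: list[DesignParams]
    design_array: np.ndarray  # (n, 3)
    coords: np.ndarray  # (n, N, 3)
    stress: np.ndarray  # (n, N, 3)
    mesh: LeafletMesh2D  # mesh of the first design (ordering shared by all)
    config: SyntheticConfig
    manifest: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[1]

    def shape_matrix(self) -> np.ndarray:
        return self.coords.reshape(self.n_samples, -1)

    def stress_matrix(self) -> np.ndarray:
        return self.stress.reshape(self.n_samples, -1)

    def samples(self) -> list[FieldSample]:
        return [
            FieldSample(d, self.coords[i], self.stress[i])
            for i, d in enumerate(self.designs)
        ]


def generate_dataset(
    designs: Sequence[DesignParams],
    cfg: SyntheticConfig | None = None,
    target_nodes: int = 1381,
) -> list[FieldSample]:
    """One FieldSample per design, with constant node count and ordering."""
    return build_dataset(designs, cfg, target_nodes).samples()


def build_dataset(
    designs: Sequence[DesignParams],
    cfg: SyntheticConfig | None = None,
    target_nodes: int = 1381,
) -> FieldDataset:
    """Generate the full study as aligned arrays (preferred for training)."""
    cfg = cfg or SyntheticConfig()
    designs = list(designs)
    if cfg.low_rank:
        return _build_low_rank_dataset(designs, cfg, target_nodes)

    coords_list, stress_list = [], []
    mesh0: LeafletMesh2D | None = None
    for i, d in enumerate(designs):
        try:
            sample, mesh = _simulate_design(d, cfg, target_nodes, i)
        except GeometryError as err:
            raise GeometryError(f"design_id={i} ({d}): {err}") from err
        if mesh0 is None:
            mesh0 = mesh
        coords_list.append(sample.deformed_coords)
        stress_list.append(sample.stress)
    return FieldDataset(
        designs=designs,
        design_array=designs_to_array(designs),
        coords=np.array(coords_list),
        stress=np.array(stress_list),
        mesh=mesh0,
        config=cfg,
        manifest=_manifest(cfg, target_nodes, len(designs)),
    )


def _build_low_rank_dataset(
    designs: list[DesignParams], cfg: SyntheticConfig, target_nodes: int
) -> FieldDataset:
    if cfg.n_modes != 8:
        raise ValueError("low-rank mode is defined for exactly 8 modes")
    space = DesignSpace.default()
    nominal = DesignParams(*(0.5 * (space.lows() + space.highs())))
    base_cfg = replace(cfg, low_rank=False, noise_sd=0.0)
    base, mesh = _simulate_design(nominal, base_cfg, target_nodes, 0)
    shape_basis, stress_basis = _low_rank_bases(mesh)

    n = len(designs)
    coeffs = np.array([_mode_coefficients(d) for d in designs])  # (n, 8)
    coords = base.flat_shape()[None, :] + 0.5 * coeffs @ shape_basis
    stress = base.flat_stress()[None, :] + 60.0 * coeffs @ stress_basis
    coords = coords.reshape(n, mesh.n_nodes, 3)
    stress = stress.reshape(n, mesh.n_nodes, 3)
    if cfg.noise_sd > 0:
        for i in range(n):
            rng = np.random.default_rng([cfg.seed, i])
            stress[i] *= 1.0 + cfg.noise_sd * rng.standard_normal(stress[i].shape)
            coords[i] *= 1.0 + cfg.noise_sd * rng.standard_normal(coords[i].shape)
    return FieldDataset(
        designs=designs,
        design_array=designs_to_array(designs),
        coords=coords,
        stress=stress,
        mesh=mesh,
        config=cfg,
        manifest=_manifest(cfg, target_nodes, n),
    )


def _manifest(cfg: SyntheticConfig, target_nodes: int, n: int) -> dict:
    return {
        "version": DATASET_VERSION,
        "seed": cfg.seed,
        "n_samples": n,
        "target_nodes": target_nodes,
        "pressure_mmHg": cfg.pressure,
        "noise_sd": cfg.noise_sd,
        "stress_scale_kPa": list(cfg.stress_scale),
        "low_rank": cfg.low_rank,
    }
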