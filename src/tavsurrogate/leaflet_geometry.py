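"""Parametric TAV leaflet geometry: 2D contour, structured mesh, 3D suturing curve.

The flat (pre-assembly) leaflet is a scallop bounded below by the attachment
edge ``ya(x) = a * exp(0.1053 * x**2)`` and above by the free edge, an offset of
``yf(x) = h * (1 - (exp(x**3 - m**3) - 1) / (exp(-m**3) - 1))`` with
``m = 10.9`` mm, where the free-edge height follows
``h = h_nom + r * (SSL - SSL_nom)`` with ``h_nom = 13.3`` mm,
``SSL_nom = 19.1`` mm and ``r = 9.6``.  The leaflet half-width is the value
``xmax`` at which the attachment-edge arc length over ``[-xmax, xmax]`` equals
the design's SSL, so the suturing-line length is conserved between the 2D blank
and the 3D stent curve ``z = p * exp(b * |theta|)`` (``p = 0.20`` mm, one
leaflet spanning a third of the stent circumference).

All constructions are deterministic; node count and ordering are identical
across designs so nodal fields are comparable vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .design_space import DesignParams
from .exceptions import ConfigError, ConsistencyError, GeometryError

# Printed geometric constants (mm unless dimensionless).
ATTACHMENT_COEF = 0.1053  # mm^-2, exponent coefficient of the attachment curve
FREE_EDGE_M = 10.9  # free-edge shape constant m
H_NOM = 13.3  # nominal free-edge height
SSL_NOM = 19.1  # nominal suturing-line length
H_SLOPE = 9.6  # dh/dSSL
SSL_Z0 = 0.20  # p: SSL height at theta = 0
THETA_SPAN = math.pi / 3.0  # half angular span of one leaflet (3 leaflets/valve)

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(16)


def free_edge_height(ssl: float) -> float:
    """Free-edge height h(SSL) = h_nom + r * (SSL - SSL_nom), in mm."""
    if not math.isfinite(ssl):
        raise ConfigError("ssl must be finite")
    return H_NOM + H_SLOPE * (ssl - SSL_NOM)


def attachment_y(x, a: float):
    """Attachment-edge curve ya(x) = a * exp(0.1053 * x**2)."""
    x = np.asarray(x, dtype=float)
    y = a * np.exp(ATTACHMENT_COEF * x**2)
    return y if y.ndim else float(y)


def _attachment_dy(x, a: float):
    x = np.asarray(x, dtype=float)
    return 2.0 * ATTACHMENT_COEF * a * x * np.exp(ATTACHMENT_COEF * x**2)


def free_edge_y(x, h: float, m: float = FREE_EDGE_M):
    """Free-edge profile yf(x) on |x| <= m; yf(0) = 0 and yf(+-m) = h.

    The cubic is taken in |x| so the profile is symmetric like the leaflet.
    Evaluated with ``expm1`` so the extreme exponents (|x|**3 - m**3 is of
    order -1e3 over most of the domain) neither overflow nor lose the boundary
    identities.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > m):
        raise GeometryError(f"free_edge_y domain is |x| <= m = {m}")
    ax = np.abs(x)
    # factored |x|^3 - m^3: exactly zero at |x| = m, so yf(+-m) = h exactly
    expo = (ax - m) * (ax * ax + ax * m + m * m)
    num = np.expm1(expo)
    den = np.expm1(-(m * m * m))
    y = h * (1.0 - num / den)
    return y if y.ndim else float(y)


def attachment_arc_length(a: float, xmax: float) -> float:
    """Arc length of ya over [-xmax, xmax] by adaptive quadrature."""
    integrand = lambda x: math.hypot(1.0, float(_attachment_dy(x, a)))
    val, _ = quad(integrand, 0.0, xmax, limit=200)
    return 2.0 * val


def solve_half_width(a: float, ssl: float) -> float:
    """xmax > 0 with attachment arc length over [-xmax, xmax] equal to ssl.

    The arc length is strictly increasing in xmax, so the root is unique; it is
    bracketed on (0, 2m] and refined to ~1e-12 relative accuracy.
    """
    hi = 2.0 * FREE_EDGE_M
    f = lambda x: attachment_arc_length(a, x) - ssl
    if f(hi) < 0.0:
        raise GeometryError(
            f"attachment arc length cannot reach ssl={ssl} within xmax <= {hi}"
        )
    xmax = brentq(f, 1e-9, hi, xtol=1e-13, rtol=1e-14)
    return float(xmax)


@dataclass(frozen=True)
class Contour2D:
    """Closed 2D leaflet contour.

    The free edge stored here is the yf profile shifted vertically by
    ``free_edge_offset`` so that the two edges meet at ``x = +-half_width``.
    """

    attachment_points: np.ndarray  # (n, 2), ordered -xmax -> +xmax
    free_edge_points: np.ndarray  # (n, 2), same x stations
    half_width: float  # xmax, mm
    h: float  # free-edge height parameter, mm
    a: float  # attachment coefficient, mm
    ssl: float  # suturing-line length, mm
    free_edge_offset: float  # vertical shift applied to yf, mm
    arc_length: float = field(default=float("nan"))  # attachment arc length, mm

    def attachment_at(self, x):
        return attachment_y(x, self.a)

    def free_edge_at(self, x):
        return free_edge_y(x, self.h) + self.free_edge_offset


def build_contour(p: DesignParams, n_points: int = 199) -> Contour2D:
    """Build the closed 2D contour for one design.

    ``n_points`` sets the sampling resolution of the stored point lists; the
    analytic curves are kept on the object so meshing can resample them.
    """
    h = free_edge_height(p.ssl)
    xmax = solve_half_width(p.a, p.ssl)
    offset = float(attachment_y(xmax, p.a)) - float(free_edge_y(xmax, h))
    xs = np.linspace(-xmax, xmax, n_points)
    att = np.column_stack([xs, attachment_y(xs, p.a)])
    free = np.column_stack([xs, free_edge_y(xs, h) + offset])
    return Contour2D(
        attachment_points=att,
        free_edge_points=free,
        half_width=xmax,
        h=h,
        a=p.a,
        ssl=p.ssl,
        free_edge_offset=offset,
        arc_length=attachment_arc_length(p.a, xmax),
    )


@dataclass(frozen=True)
class LeafletMesh2D:
    """Structured triangulation of the flat leaflet.

    Nodes are ordered: left commissure, then columns of ``n_rows`` nodes from
    the attachment edge (v = 0) to the free edge (v = 1) sweeping left to
    right, then the right commissure.  ``node_u``/``node_v`` are the parametric
    coordinates of each node (u along the attachment edge, v across).  The same
    ``target_nodes`` always produces the same ordering, so nodal fields from
    different designs are aligned component-wise.
    """

    nodes: np.ndarray  # (N, 2) mm
    triangles: np.ndarray  # (M, 3) int
    attachment_node_ids: np.ndarray  # ordered along the attachment edge
    free_edge_node_ids: np.ndarray  # ordered along the free edge
    commissure_node_ids: tuple[int, int]
    node_u: np.ndarray  # (N,)
    node_v: np.ndarray  # (N,)
    n_rows: int
    n_cols: int  # interior columns (commissures excluded)
    contour: Contour2D | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]


def _grid_factorization(target_nodes: int) -> tuple[int, int]:
    """Split target_nodes = inner_cols * n_rows + 2 commissure nodes.

    ``n_rows`` is the divisor of ``target_nodes - 2`` closest to
    ``sqrt((target_nodes - 2) / 3)`` (a wide, roughly 3:1 grid); the default
    1381 nodes factor as 197 columns x 7 rows + 2.
    """
    inner_total = target_nodes - 2
    if inner_total < 4:
        raise ConfigError(f"target_nodes={target_nodes} too small")
    divisors = [d for d in range(2, int(math.isqrt(inner_total)) + 1) if inner_total % d == 0]
    divisors += [inner_total // d for d in divisors if d != inner_total // d]
    candidates = [d for d in divisors if 2 <= d <= inner_total // d]
    if not candidates:
        raise ConfigError(
            f"target_nodes={target_nodes} not realizable by the structured grid "
            f"(no factorization of {inner_total} with >= 2 rows)"
        )
    ideal = math.sqrt(inner_total / 3.0)
    n_rows = min(candidates, key=lambda d: (abs(d - ideal), d))
    return inner_total // n_rows, n_rows


def mesh_leaflet(c: Contour2D, target_nodes: int = 1381) -> LeafletMesh2D:
    """Transfinite structured triangulation between the two contour edges.

    Columns sit at equispaced x stations; the two end stations collapse to the
    commissure points where the edges meet.
    """
    inner, n_rows = _grid_factorization(target_nodes)
    xs = np.linspace(-c.half_width, c.half_width, inner + 2)
    v = np.linspace(0.0, 1.0, n_rows)
    u = (xs + c.half_width) / (2.0 * c.half_width)

    y_bot = np.asarray(c.attachment_at(xs))
    y_top = np.asarray(c.free_edge_at(xs))

    n_nodes = inner * n_rows + 2
    nodes = np.empty((n_nodes, 2))
    node_u = np.empty(n_nodes)
    node_v = np.empty(n_nodes)

    nodes[0] = (xs[0], y_bot[0])
    node_u[0], node_v[0] = 0.0, 0.0
    nodes[-1] = (xs[-1], y_bot[-1])
    node_u[-1], node_v[-1] = 1.0, 0.0

    def col(i: int) -> np.ndarray:  # node ids of interior column i (1-based station)
        start = 1 + (i - 1) * n_rows
        return np.arange(start, start + n_rows)

    for i in range(1, inner + 1):
        ids = col(i)
        nodes[ids, 0] = xs[i]
        nodes[ids, 1] = y_bot[i] + v * (y_top[i] - y_bot[i])
        node_u[ids] = u[i]
        node_v[ids] = v

    tris: list[tuple[int, int, int]] = []
    first, last = col(1), col(inner)
    for j in range(n_rows - 1):
        tris.append((0, first[j], first[j + 1]))
    for i in range(1, inner):
        a_ids, b_ids = col(i), col(i + 1)
        for j in range(n_rows - 1):
            pa, pb, pc, pd = a_ids[j], b_ids[j], b_ids[j + 1], a_ids[j + 1]
            tris.append((pa, pb, pc))
            tris.append((pa, pc, pd))
    for j in range(n_rows - 1):
        tris.append((last[j], n_nodes - 1, last[j + 1]))
    triangles = np.array(tris, dtype=np.int64)

    areas = _triangle_areas(nodes, triangles)
    if np.any(areas <= 0.0):
        raise GeometryError("degenerate (non-positive area) triangle in leaflet mesh")

    attachment_ids = np.concatenate(
        [[0], [col(i)[0] for i in range(1, inner + 1)], [n_nodes - 1]]
    ).astype(np.int64)
    free_ids = np.concatenate(
        [[0], [col(i)[-1] for i in range(1, inner + 1)], [n_nodes - 1]]
    ).astype(np.int64)

    return LeafletMesh2D(
        nodes=nodes,
        triangles=triangles,
        attachment_node_ids=attachment_ids,
        free_edge_node_ids=free_ids,
        commissure_node_ids=(0, n_nodes - 1),
        node_u=node_u,
        node_v=node_v,
        n_rows=n_rows,
        n_cols=inner,
        contour=c,
    )


def _triangle_areas(nodes: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p0 = nodes[triangles[:, 0]]
    p1 = nodes[triangles[:, 1]]
    p2 = nodes[triangles[:, 2]]
    d1, d2 = p1 - p0, p2 - p0
    return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])


def mesh_area(mesh: LeafletMesh2D) -> float:
    """Total signed area covered by the triangulation."""
    return float(np.sum(_triangle_areas(mesh.nodes, mesh.triangles)))


@dataclass(frozen=True)
class SSLCurve3D:
    """Stent suturing line z = p * exp(b * |theta|) on a cylinder of solved radius.

    theta runs over [-pi/3, pi/3] (one of three identical leaflets); the
    cylinder radius is the free variable chosen so the 3D arc length equals the
    design SSL.
    """

    theta_samples: np.ndarray  # rad
    radius: float  # mm
    z_values: np.ndarray  # mm
    p: float  # mm
    b: float
    ssl: float  # mm
    theta_max: float = THETA_SPAN

    def z_at(self, theta):
        theta = np.asarray(theta, dtype=float)
        z = self.p * np.exp(self.b * np.abs(theta))
        return z if z.ndim else float(z)

    def point(self, theta):
        """Cartesian point(s) on the curve; stent axis along z, leaflet at theta=0."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        pts = np.column_stack(
            [self.radius * np.cos(theta), self.radius * np.sin(theta), self.z_at(theta)]
        )
        return pts

    def arc_length(self) -> float:
        return _ssl_arc_length(self.radius, self.b, self.p, self.theta_max)


def _ssl_arc_length(radius: float, b: float, p: float, theta_max: float) -> float:
    integrand = lambda t: math.sqrt(radius**2 + (p * b * math.exp(b * t)) ** 2)
    val, _ = quad(integrand, 0.0, theta_max, limit=200)
    return 2.0 * val


def build_ssl_curve(b: float, ssl: float, n_samples: int = 201) -> SSLCurve3D:
    """Solve the stent cylinder radius so the SSL curve arc length equals ssl."""
    f = lambda r: _ssl_arc_length(r, b, SSL_Z0, THETA_SPAN) - ssl
    lo, hi = 1e-9, ssl
    if f(lo) > 0.0 or f(hi) < 0.0:
        raise GeometryError(
            f"cannot bracket stent radius for b={b}, ssl={ssl}: the z-branch alone "
            "is longer than ssl or the bracket is too small"
        )
    radius = brentq(f, lo, hi, xtol=1e-13, rtol=1e-14)
    thetas = np.linspace(-THETA_SPAN, THETA_SPAN, n_samples)
    return SSLCurve3D(
        theta_samples=thetas,
        radius=float(radius),
        z_values=SSL_Z0 * np.exp(b * np.abs(thetas)),
        p=SSL_Z0,
        b=b,
        ssl=ssl,
    )


def check_same_design(mesh: LeafletMesh2D, curve: SSLCurve3D, rtol: float = 1e-6) -> None:
    """Raise ConsistencyError unless mesh and curve share the same SSL."""
    if mesh.contour is None:
        raise ConsistencyError("mesh has no contour attached; cannot verify design")
    if not math.isclose(mesh.contour.ssl, curve.ssl, rel_tol=rtol):
        raise ConsistencyError(
            f"mesh ssl={mesh.contour.ssl} and curve ssl={curve.ssl} disagree"
        )


def gauss_cumulative_arc(dy_dx, xs: np.ndarray) -> np.ndarray:
    """Cumulative arc length of y(x) at the stations ``xs`` (16-pt Gauss per segment)."""
    xs = np.asarray(xs, dtype=float)
    x0, x1 = xs[:-1], xs[1:]
    halves = 0.5 * (x1 - x0)
    mids = 0.5 * (x0 + x1)
    pts = mids[:, None] + halves[:, None] * _GL_NODES[None, :]
    seg = halves * np.sum(_GL_WEIGHTS[None, :] * np.hypot(1.0, dy_dx(pts)), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def attachment_cumulative_arc(c: Contour2D, xs: np.ndarray) -> np.ndarray:
    return gauss_cumulative_arc(lambda x: _attachment_dy(x, c.a), xs)
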