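import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tavsurrogate as tv
from tavsurrogate.exceptions import ConfigError, GeometryError
from tavsurrogate.leaflet_geometry import (
    FREE_EDGE_M,
    attachment_arc_length,
    attachment_cumulative_arc,
    mesh_area,
)


class TestFreeEdgeHeight:
    @pytest.mark.parametrize(
        "ssl, expected",
        [
            (19.1, 13.3),  # nominal SSL gives the nominal height
            (18.4, 13.3 + 9.6 * (18.4 - 19.1)),  # 6.58 mm
            (20.1, 13.3 + 9.6 * (20.1 - 19.1)),  # 22.9 mm
        ],
    )
    def test_linear_in_ssl(self, ssl, expected):
        assert tv.free_edge_height(ssl) == pytest.approx(expected, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ConfigError):
            tv.free_edge_height(float("nan"))


class TestAttachmentCurve:
    def test_value_at_origin_is_a(self):
        assert tv.attachment_y(0.0, 4.57) == 4.57

    def test_scalar_value_against_high_precision_oracle(self):
        import sympy

        expected = float(4.57 * sympy.exp(sympy.Rational(1053, 10000) * 1**2))
        assert tv.attachment_y(1.0, 4.57) == pytest.approx(expected, rel=1e-15)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=-5, max_value=5))
    def test_even_function(self, x):
        assert tv.attachment_y(x, 5.0) == tv.attachment_y(-x, 5.0)


class TestFreeEdgeCurve:
    def test_boundary_values(self):
        h = 13.3
        assert tv.free_edge_y(FREE_EDGE_M, h) == pytest.approx(h, abs=1e-12)
        assert tv.free_edge_y(-FREE_EDGE_M, h) == pytest.approx(h, abs=1e-12)
        assert tv.free_edge_y(0.0, h) == pytest.approx(0.0, abs=1e-15)

    def test_outside_domain_raises(self):
        with pytest.raises(GeometryError):
            tv.free_edge_y(FREE_EDGE_M + 0.01, 13.3)

    def test_near_corner_against_arbitrary_precision_oracle(self):
        # exponents are extreme near |x| = m; compare with mpmath at 60 digits
        import sympy
        from sympy import E, Float, Rational

        h, m = Rational(133, 10), Rational(109, 10)
        x = Float("0.99", 60) * m
        expr = h * (1 - (E ** (x**3 - m**3) - 1) / (E ** (-(m**3)) - 1))
        expected = float(expr.evalf(60))
        got = tv.free_edge_y(float(0.99 * 10.9), float(h))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_abs_x(self):
        xs = np.linspace(0.0, FREE_EDGE_M, 200)
        ys = tv.free_edge_y(xs, 13.3)
        assert np.all(np.diff(ys) >= -1e-15)


class TestHalfWidth:
    def test_defining_arc_length_property(self):
        xmax = tv.solve_half_width(5.0, 19.0)
        assert attachment_arc_length(5.0, xmax) == pytest.approx(19.0, rel=1e-9)

    def test_monotone_in_ssl(self):
        assert tv.solve_half_width(5.0, 20.0) > tv.solve_half_width(5.0, 18.5)

    def test_against_brute_force_scan(self):
        # tabulate arc length on a dense xmax grid and invert by bisection on it
        a, ssl = 5.0, 19.0
        xs = np.linspace(0.0, 5.0, 200001)
        dx = xs[1] - xs[0]
        seg = np.hypot(np.diff(xs), np.diff(a * np.exp(0.1053 * xs**2)))
        half_arc = np.concatenate([[0.0], np.cumsum(seg)])
        brute = xs[np.searchsorted(2.0 * half_arc, ssl)]
        assert tv.solve_half_width(a, ssl) == pytest.approx(brute, abs=3 * dx)


class TestContour:
    def test_arc_length_invariant_and_symmetry(self, nominal_design, small_contour):
        c = small_contour
        assert c.arc_length == pytest.approx(nominal_design.ssl, rel=1e-6)
        att = c.attachment_points
        assert np.allclose(att[:, 1], att[::-1, 1], atol=1e-12)
        assert np.allclose(att[:, 0], -att[::-1, 0], atol=1e-12)
        free = c.free_edge_points
        assert np.allclose(free[:, 1], free[::-1, 1], atol=1e-12)

    def test_edges_meet_at_half_width(self, small_contour):
        c = small_contour
        assert c.attachment_points[-1] == pytest.approx(c.free_edge_points[-1])
        assert abs(c.attachment_points[-1][0]) == pytest.approx(c.half_width)

    def test_ssl_controls_half_width(self):
        c1 = tv.build_contour(tv.DesignParams(5.0, 3.2, 18.5))
        c2 = tv.build_contour(tv.DesignParams(5.0, 3.2, 20.0))
        assert c2.half_width > c1.half_width

    def test_free_edge_uses_height_law(self, small_contour, nominal_design):
        assert small_contour.h == pytest.approx(
            tv.free_edge_height(nominal_design.ssl)
        )


class TestMesh:
    def test_default_node_count_is_1381(self, nominal_design):
        c = tv.build_contour(nominal_design)
        m = tv.mesh_leaflet(c, 1381)
        assert m.n_nodes == 1381
        assert m.n_cols * m.n_rows + 2 == 1381

    def test_deterministic_construction(self, small_contour):
        m1 = tv.mesh_leaflet(small_contour, 121)
        m2 = tv.mesh_leaflet(small_contour, 121)
        assert np.array_equal(m1.nodes, m2.nodes)
        assert np.array_equal(m1.triangles, m2.triangles)

    def test_area_matches_shoelace_of_boundary_polygon(self, small_mesh):
        m = small_mesh
        att = m.nodes[m.attachment_node_ids]
        free = m.nodes[m.free_edge_node_ids]
        poly = np.vstack([att, free[::-1][1:-1]])
        x, y = poly[:, 0], poly[:, 1]
        shoelace = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        assert mesh_area(m) == pytest.approx(shoelace, rel=1e-12)

    def test_boundary_nodes_lie_on_contour_curves(self, small_mesh):
        m, c = small_mesh, small_mesh.contour
        att = m.nodes[m.attachment_node_ids]
        assert np.allclose(att[:, 1], c.attachment_at(att[:, 0]), atol=1e-12)
        free = m.nodes[m.free_edge_node_ids[1:-1]]
        assert np.allclose(free[:, 1], c.free_edge_at(free[:, 0]), atol=1e-12)

    def test_no_degenerate_triangles(self, small_mesh):
        p = small_mesh.nodes[small_mesh.triangles]
        d1, d2 = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]
        areas = 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
        assert np.all(areas > 0)

    def test_unrealizable_node_count_rejected(self, small_contour):
        # 13 - 2 = 11 is prime: no structured grid with >= 2 rows exists
        with pytest.raises(ConfigError):
            tv.mesh_leaflet(small_contour, 13)


class TestSSLCurve:
    def test_z_at_origin_is_p(self):
        curve = tv.build_ssl_curve(3.2, 19.1)
        assert curve.z_at(0.0) == pytest.approx(0.20, abs=1e-15)

    def test_arc_length_equals_ssl(self):
        curve = tv.build_ssl_curve(3.0, 18.4)
        assert curve.arc_length() == pytest.approx(18.4, rel=1e-9)

    def test_z_strictly_increases_with_abs_theta(self):
        curve = tv.build_ssl_curve(3.4, 20.1)
        pos = curve.theta_samples[curve.theta_samples >= 0]
        assert np.all(np.diff(curve.z_at(pos)) > 0)

    def test_radius_against_brute_force_scan(self):
        b, ssl = 3.2, 19.1
        radii = np.linspace(1.0, 12.0, 30001)
        theta = np.linspace(0.0, math.pi / 3.0, 4001)
        dz = 0.20 * b * np.exp(b * theta)
        # trapezoid arc length for every candidate radius
        ds = np.sqrt(radii[:, None] ** 2 + dz[None, :] ** 2)
        arcs = 2.0 * np.trapezoid(ds, theta, axis=1)
        brute = radii[np.argmin(np.abs(arcs - ssl))]
        curve = tv.build_ssl_curve(b, ssl)
        assert curve.radius == pytest.approx(brute, abs=1e-3)


def test_ssl_conservation_2d_equals_3d():
    """The suturing-line length is conserved between the flat blank and 3D curve."""
    for d in tv.sample_designs(n=10, seed=3):
        c = tv.build_contour(d, n_points=9)
        curve = tv.build_ssl_curve(d.b, d.ssl)
        assert c.arc_length == pytest.approx(d.ssl, rel=1e-6)
        assert curve.arc_length() == pytest.approx(d.ssl, rel=1e-6)


def test_cumulative_arc_matches_total():
    c = tv.build_contour(tv.DesignParams(5.0, 3.2, 19.0), n_points=33)
    xs = np.linspace(-c.half_width, c.half_width, 33)
    cum = attachment_cumulative_arc(c, xs)
    assert cum[-1] == pytest.approx(c.arc_length, rel=1e-12)
    assert np.all(np.diff(cum) > 0)
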