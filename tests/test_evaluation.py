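import numpy as np
import pytest

from tavsurrogate.evaluation import (
    circumcircle_radius,
    mean_predictor_report,
    monte_carlo_cv,
    shape_errors,
    stress_errors,
    valve_commissure_points,
)
from tavsurrogate.exceptions import ConfigError, GeometryError


class TestCircumcircle:
    def test_equilateral_closed_form(self):
        s = 2.0
        pts = np.array([[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0]])
        assert circumcircle_radius(pts) == pytest.approx(s / np.sqrt(3), rel=1e-12)

    def test_unit_circle_example(self):
        pts = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0]], dtype=float)
        assert circumcircle_radius(pts) == pytest.approx(1.0, rel=1e-12)

    def test_rotation_invariance(self, rng):
        pts = rng.normal(size=(3, 3))
        r0 = circumcircle_radius(pts)
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert circumcircle_radius(pts @ q.T) == pytest.approx(r0, rel=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]], dtype=float)
        with pytest.raises(GeometryError):
            circumcircle_radius(pts)

    def test_valve_commissures_are_threefold_symmetric(self, tiny_dataset):
        pts = valve_commissure_points(
            tiny_dataset.coords[0], tiny_dataset.mesh.commissure_node_ids
        )
        d01 = np.linalg.norm(pts[0] - pts[1])
        d12 = np.linalg.norm(pts[1] - pts[2])
        d20 = np.linalg.norm(pts[2] - pts[0])
        assert d01 == pytest.approx(d12) == pytest.approx(d20)
        assert np.allclose(pts[:, 2], pts[0, 2])


class TestShapeErrors:
    def test_identity_gives_zero(self, rng):
        x = rng.normal(size=(30, 3))
        e = shape_errors(x, x, R=10.0)
        assert (e.mean_e, e.n_mean_e, e.max_e, e.n_max_e) == (0, 0, 0, 0)

    def test_two_node_worked_example(self):
        truth = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        pred = np.array([[3.0, 0, 0], [10.0, 4.0, 0]])  # distances 3 and 4 mm
        e = shape_errors(truth, pred, R=10.0)
        assert e.mean_e == pytest.approx(3.5)
        assert e.n_mean_e == pytest.approx(35.0)
        assert e.max_e == pytest.approx(4.0)
        assert e.n_max_e == pytest.approx(40.0)

    def test_rigid_translation(self, rng):
        x = rng.normal(size=(20, 3))
        shift = np.array([0.3, -0.4, 1.2])
        e = shape_errors(x, x + shift, R=5.0)
        d = np.linalg.norm(shift)
        assert e.mean_e == pytest.approx(d) and e.max_e == pytest.approx(d)

    def test_mean_never_exceeds_max(self, rng):
        for _ in range(20):
            t = rng.normal(size=(15, 3))
            p = t + rng.normal(size=(15, 3))
            e = shape_errors(t, p, R=3.0)
            assert e.mean_e <= e.max_e

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            shape_errors(np.zeros((3, 3)), np.zeros((4, 3)), R=1.0)


class TestStressErrors:
    def test_identity_gives_zero(self, rng):
        s = rng.normal(size=50)
        e = stress_errors(s, s)
        assert (e.mean_e, e.n_mean_e, e.max_e, e.n_max_e) == (0, 0, 0, 0)

    def test_three_value_worked_example(self):
        e = stress_errors(np.array([10.0, -20.0, 5.0]), np.array([12.0, -18.0, 5.0]))
        assert e.mean_e == pytest.approx(4.0 / 3.0)
        assert e.n_mean_e == pytest.approx(100.0 * (4.0 / 3.0) / 30.0)
        assert e.max_e == pytest.approx(2.0)  # peak |.|: 20 vs 18
        assert e.n_max_e == pytest.approx(10.0)

    def test_sign_flip_leaves_peak_error_unchanged(self, rng):
        t = rng.normal(size=40)
        p = t + 0.1 * rng.normal(size=40)
        assert stress_errors(t, p).max_e == pytest.approx(stress_errors(-t, -p).max_e)

    def test_constant_truth_field_flagged(self):
        with pytest.raises(ConfigError):
            stress_errors(np.full(5, 3.0), np.arange(5.0))


class TestBruteForceEquivalence:
    """The vectorized metrics must match naive per-node loops exactly."""

    def test_shape_metrics_match_naive_loops(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 12))
            t = rng.normal(size=(n, 3))
            p = t + rng.normal(size=(n, 3))
            R = float(rng.uniform(1.0, 20.0))
            dists = [float(np.sqrt(sum((t[i, k] - p[i, k]) ** 2 for k in range(3))))
                     for i in range(n)]
            e = shape_errors(t, p, R)
            assert e.mean_e == pytest.approx(sum(dists) / n, rel=1e-12)
            assert e.max_e == pytest.approx(max(dists), rel=1e-12)
            assert e.n_mean_e == pytest.approx(100 * sum(dists) / n / R, rel=1e-12)
            assert e.n_max_e == pytest.approx(100 * max(dists) / R, rel=1e-12)

    def test_stress_metrics_match_naive_loops(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 15))
            t = rng.normal(size=n) * 10
            p = t + rng.normal(size=n)
            e = stress_errors(t, p)
            mean_e = sum(abs(t[i] - p[i]) for i in range(n)) / n
            rng_t = max(t) - min(t)
            max_e = abs(max(abs(v) for v in t) - max(abs(v) for v in p))
            assert e.mean_e == pytest.approx(mean_e, rel=1e-12)
            assert e.n_mean_e == pytest.approx(100 * mean_e / rng_t, rel=1e-12)
            assert e.max_e == pytest.approx(max_e, rel=1e-12)
            assert e.n_max_e == pytest.approx(
                100 * max_e / max(abs(v) for v in t), rel=1e-12
            )


class TestMonteCarloCV:
    def test_seeded_protocol_is_reproducible(self, tiny_dataset):
        r1 = monte_carlo_cv(tiny_dataset, "mean_baseline", "shape", rho=50,
                            repeats=3, seed=11)
        r2 = monte_carlo_cv(tiny_dataset, "mean_baseline", "shape", rho=50,
                            repeats=3, seed=11)
        assert r1.metrics == r2.metrics
        assert np.array_equal(r1.per_sample_mean_e["shape"],
                              r2.per_sample_mean_e["shape"])

    def test_different_seed_changes_splits(self, tiny_dataset):
        r1 = monte_carlo_cv(tiny_dataset, "mean_baseline", "shape", rho=50,
                            repeats=3, seed=11)
        r3 = monte_carlo_cv(tiny_dataset, "mean_baseline", "shape", rho=50,
                            repeats=3, seed=12)
        assert r1.metrics != r3.metrics

    def test_stress_metrics_reported_per_component(self, tiny_dataset):
        r = monte_carlo_cv(tiny_dataset, "mean_baseline", "stress", rho=50,
                           repeats=2, seed=0)
        for comp in ("s11", "s22", "s12"):
            for m in ("mean_e", "n_mean_e", "max_e", "n_max_e"):
                assert f"{comp}_{m}" in r.metrics

    def test_identical_samples_give_zero_baseline_error(self, tiny_dataset):
        import copy

        ds = copy.copy(tiny_dataset)
        ds.coords = np.repeat(tiny_dataset.coords[:1], 10, axis=0)
        ds.stress = np.repeat(tiny_dataset.stress[:1], 10, axis=0)
        ds.design_array = np.repeat(tiny_dataset.design_array[:1], 10, axis=0)
        r = monte_carlo_cv(ds, "mean_baseline", "shape", rho=50, repeats=2, seed=1)
        assert r.mean("mean_e") == pytest.approx(0.0, abs=1e-12)

    def test_invalid_rho_and_repeats_rejected(self, tiny_dataset):
        with pytest.raises(ConfigError):
            monte_carlo_cv(tiny_dataset, "mean_baseline", "shape", rho=0, repeats=1)
        with pytest.raises(ConfigError):
            monte_carlo_cv(tiny_dataset, "mean_baseline", "shape", rho=50, repeats=0)
        with pytest.raises(ConfigError):
            monte_carlo_cv(tiny_dataset, "model_x", "shape", rho=50, repeats=1)

    def test_baseline_report_bookkeeping(self, tiny_dataset):
        rep = mean_predictor_report(tiny_dataset, "shape", rho=50, repeats=4, seed=2)
        n_test = tiny_dataset.n_samples - round(0.5 * tiny_dataset.n_samples)
        assert rep["shape"].shape == (4 * n_test,)
        assert np.all(rep["shape"] >= 0)
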