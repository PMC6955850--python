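"""Error metrics and the Monte-Carlo cross-validation protocol.

Shape metrics compare true and predicted deformed meshes node by node:
MeanE is the mean Euclidean node distance (mm), MaxE the largest one;
their normalized versions divide by the radius R of the circumcircle through
the valve's three commissures on the true valve and are reported in percent.

Stress metrics are computed per component (S11, S22, S12): MeanE is the mean
absolute nodal difference (kPa), NMeanE normalizes by the true component's
range, MaxE compares the *peak absolute* stresses of the two fields (the peak
locations may differ) and NMaxE normalizes by the true peak.

Monte-Carlo cross-validation draws rho% of the designs (without replacement)
as training data, trains the requested model family from scratch, evaluates
the complement, and repeats with independently seeded splits, reporting the
mean and standard deviation of every metric across repeats.  A mean-predictor
baseline (always output the training-mean field) provides the reference scale
of the data variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, GeometryError
from .synthetic_fea import FieldDataset
from .training import TrainConfig, fit_model_a, fit_model_d

MODEL_FAMILIES = ("model_a", "model_d", "mean_baseline")
SHAPE_METRICS = ("mean_e", "n_mean_e", "max_e", "n_max_e")
STRESS_COMPONENTS = ("s11", "s22", "s12")


@dataclass(frozen=True)
class ShapeErrors:
    """Shape error set: mean_e/max_e in mm, normalized versions in percent."""

    mean_e: float
    n_mean_e: float
    max_e: float
    n_max_e: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_e": self.mean_e,
            "n_mean_e": self.n_mean_e,
            "max_e": self.max_e,
            "n_max_e": self.n_max_e,
        }


@dataclass(frozen=True)
class StressErrors:
    """Per-component stress errors: mean_e/max_e in kPa, normalized in percent."""

    mean_e: float
    n_mean_e: float
    max_e: float
    n_max_e: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_e": self.mean_e,
            "n_mean_e": self.n_mean_e,
            "max_e": self.max_e,
            "n_max_e": self.n_max_e,
        }


def circumcircle_radius(points: np.ndarray) -> float:
    """Radius of the unique circle through three non-collinear 3D points."""
    pts = np.asarray(points, dtype=float)
    if pts.shape != (3, 3):
        raise ConfigError("circumcircle_radius expects exactly three 3D points")
    a = np.linalg.norm(pts[1] - pts[2])
    b = np.linalg.norm(pts[0] - pts[2])
    c = np.linalg.norm(pts[0] - pts[1])
    cross = np.cross(pts[1] - pts[0], pts[2] - pts[0])
    area2 = np.linalg.norm(cross)  # twice the triangle area
    if area2 <= 1e-12 * max(a, b, c) ** 2:
        raise GeometryError("commissure points are (nearly) collinear")
    return float(a * b * c / (2.0 * area2))


def valve_commissure_points(coords: np.ndarray, commissure_node_ids) -> np.ndarray:
    """The valve's three commissures from one leaflet's deformed coordinates.

    With three identical leaflets the remaining commissures are 120-degree
    rotations of the leaflet's attachment-edge endpoint about the stent axis z.
    """
    p = np.asarray(coords)[commissure_node_ids[0]]
    out = np.empty((3, 3))
    for k in range(3):
        ang = 2.0 * np.pi * k / 3.0
        ca, sa = np.cos(ang), np.sin(ang)
        out[k] = (ca * p[0] - sa * p[1], sa * p[0] + ca * p[1], p[2])
    return out


def shape_errors(truth: np.ndarray, pred: np.ndarray, R: float) -> ShapeErrors:
    """MeanE / NMeanE / MaxE / NMaxE between true and predicted nodal positions."""
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape or truth.ndim != 2 or truth.shape[1] != 3:
        raise ConfigError("shape_errors expects matching (N, 3) arrays")
    if not R > 0:
        raise ConfigError("R must be positive")
    dist = np.linalg.norm(truth - pred, axis=1)
    mean_e = float(dist.mean())
    max_e = float(dist.max())
    return ShapeErrors(
        mean_e=mean_e,
        n_mean_e=100.0 * mean_e / R,
        max_e=max_e,
        n_max_e=100.0 * max_e / R,
    )


def stress_errors(truth: np.ndarray, pred: np.ndarray) -> StressErrors:
    """Single-component stress errors; NMeanE is undefined for constant truth."""
    truth = np.asarray(truth, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if truth.shape != pred.shape:
        raise ConfigError("stress_errors expects equal-length arrays")
    rng = float(truth.max() - truth.min())
    if rng == 0.0:
        raise ConfigError("NMeanE undefined: the true stress field is constant")
    mean_e = float(np.mean(np.abs(truth - pred)))
    peak_t = float(np.max(np.abs(truth)))
    peak_p = float(np.max(np.abs(pred)))
    max_e = abs(peak_t - peak_p)
    return StressErrors(
        mean_e=mean_e,
        n_mean_e=100.0 * mean_e / abs(rng),
        max_e=max_e,
        n_max_e=100.0 * max_e / peak_t,
    )


class _MeanPredictor:
    """Baseline 'model': always outputs the training-set mean field."""

    def __init__(self, mean_field: np.ndarray):
        self.mean_field = mean_field

    def predict(self, designs) -> np.ndarray:
        n = np.atleast_2d(np.asarray(designs)).shape[0]
        return np.tile(self.mean_field, (n, 1))


@dataclass
class CVResult:
    """Mean +- sd of every metric over Monte-Carlo repeats at one rho."""

    family: str
    target: str
    rho: float
    repeats: int
    seed: int
    metrics: dict[str, tuple[float, float]]
    per_repeat: dict[str, np.ndarray] = field(default_factory=dict)
    per_sample_mean_e: dict[str, np.ndarray] = field(default_factory=dict)

    def mean(self, name: str) -> float:
        return self.metrics[name][0]

    def sd(self, name: str) -> float:
        return self.metrics[name][1]


def _target_matrix(dataset: FieldDataset, target: str) -> np.ndarray:
    if target == "shape":
        return dataset.shape_matrix()
    if target == "stress":
        return dataset.stress_matrix()
    raise ConfigError(f"unknown target {target!r}; expected 'shape' or 'stress'")


def _fit_family(family, target, x_train, y_train, cfg, seed):
    cfg = TrainConfig(**{**(cfg.__dict__ if cfg else TrainConfig().__dict__)})
    cfg.seed = seed
    if family == "mean_baseline":
        return _MeanPredictor(y_train.mean(axis=0))
    kind = f"{family}_{target}"
    if family == "model_a":
        return fit_model_a(x_train, y_train, kind=kind, cfg=cfg)
    if family == "model_d":
        return fit_model_d(x_train, y_train, kind=kind, cfg=cfg)
    raise ConfigError(f"unknown model family {family!r}; expected {MODEL_FAMILIES}")


def _sample_metrics(dataset, target, idx, pred_row):
    """Metric dict for one test sample given its flattened prediction."""
    if target == "shape":
        truth = dataset.coords[idx]
        pred = pred_row.reshape(-1, 3)
        R = circumcircle_radius(
            valve_commissure_points(truth, dataset.mesh.commissure_node_ids)
        )
        return {"shape": shape_errors(truth, pred, R)}
    truth = dataset.stress[idx]
    pred = pred_row.reshape(-1, 3)
    return {
        comp: stress_errors(truth[:, k], pred[:, k])
        for k, comp in enumerate(STRESS_COMPONENTS)
    }


def monte_carlo_cv(
    dataset: FieldDataset,
    model_family: str,
    target: str,
    rho: float = 90.0,
    repeats: int = 100,
    seed: int = 0,
    train_cfg: TrainConfig | None = None,
) -> CVResult:
    """Repeated random train/test evaluation of one model family.

    Each repeat draws round(rho% * n) designs without replacement for training
    (the exact complement is the test set), trains from scratch with a repeat
    seed derived deterministically from the master seed, and averages the
    per-test-sample metrics.  Metric means and standard deviations are taken
    across repeats.
    """
    n = dataset.n_samples
    if n < 2:
        raise ConfigError("Monte-Carlo CV needs at least 2 samples")
    if not 0.0 < rho < 100.0:
        raise ConfigError("rho must lie strictly between 0 and 100")
    if repeats < 1:
        raise ConfigError("repeats must be >= 1")
    y_all = _target_matrix(dataset, target)
    n_train = int(round(rho / 100.0 * n))
    n_train = min(max(n_train, 1), n - 1)

    repeat_rows: list[dict[str, float]] = []
    per_sample: dict[str, list[float]] = {}
    for r in range(repeats):
        ss = np.random.SeedSequence([seed, r])
        split_rng = np.random.default_rng(ss)
        repeat_seed = int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
        perm = split_rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]

        model = _fit_family(
            model_family,
            target,
            dataset.design_array[train_idx],
            y_all[train_idx],
            train_cfg,
            repeat_seed,
        )
        preds = model.predict(dataset.design_array[test_idx])

        acc: dict[str, list[float]] = {}
        for row, idx in enumerate(test_idx):
            sample = _sample_metrics(dataset, target, idx, preds[row])
            for key, errs in sample.items():
                for mname, val in errs.as_dict().items():
                    acc.setdefault(f"{key}_{mname}" if target == "stress" else mname, []).append(val)
                per_sample.setdefault(key, []).append(errs.mean_e)
        repeat_rows.append({k: float(np.mean(v)) for k, v in acc.items()})

    names = list(repeat_rows[0])
    per_repeat = {k: np.array([row[k] for row in repeat_rows]) for k in names}
    metrics = {
        k: (float(v.mean()), float(v.std(ddof=1)) if repeats > 1 else 0.0)
        for k, v in per_repeat.items()
    }
    return CVResult(
        family=model_family,
        target=target,
        rho=rho,
        repeats=repeats,
        seed=seed,
        metrics=metrics,
        per_repeat=per_repeat,
        per_sample_mean_e={k: np.array(v) for k, v in per_sample.items()},
    )


def mean_predictor_report(
    dataset: FieldDataset,
    target: str,
    rho: float = 90.0,
    repeats: int = 100,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Histogram-ready per-test-sample MeanE values of the mean-field baseline."""
    res = monte_carlo_cv(
        dataset, "mean_baseline", target, rho=rho, repeats=repeats, seed=seed
    )
    return res.per_sample_mean_e


def cv_result_frame(result: CVResult):
    """CVResult as a tidy (metric, mean, sd) pandas DataFrame for CSV export."""
    import pandas as pd

    rows = [
        {"metric": name, "mean": m, "sd": s}
        for name, (m, s) in result.metrics.items()
    ]
    frame = pd.DataFrame(rows)
    frame.insert(0, "family", result.family)
    frame.insert(1, "target", result.target)
    frame.insert(2, "rho", result.rho)
    frame.insert(3, "repeats", result.repeats)
    return frame
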