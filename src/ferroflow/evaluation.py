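"""Metrics and diagnostic arrays for the velocity surrogates.

R^2 and RMSE are reported on the raw m/s scale (predictions are inverse
min-max transformed before scoring), which makes the identity
RMSE = sd(y_test) * sqrt(1 - R^2) hold exactly on the test sample.
Diagnostics: learning curves, partial-dependence curves and the tensor-grid
prediction surface; plotting is deliberately out of scope — everything here
returns arrays.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .hemodynamics import GridSpec


@dataclass(frozen=True)
class MetricReport:
    """Test-set performance of one model, raw m/s scale."""

    model: str
    r2: float
    rmse: float
    n_test: int

    def __post_init__(self) -> None:
        if self.r2 > 1.0 + 1e-12:
            raise ValueError("r2 cannot exceed 1")
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def r2_score(y, y_pred) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero variance in y")
    return 1.0 - float(np.sum((y - y_pred) ** 2)) / ss_tot


def rmse(y, y_pred) -> float:
    """Root mean squared error sqrt(mean((y - y_pred)^2))."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((y - y_pred) ** 2)))


def consistency_ratio(report: MetricReport, y_test) -> float:
    """rmse / (sd(y_test) * sqrt(1 - r2)) — equals 1 when the metrics come
    from the same test sample (population sd)."""
    y = np.asarray(y_test, dtype=float)
    return report.rmse / (float(np.std(y)) * float(np.sqrt(1.0 - report.r2)))


def learning_curve(
    model_factory,
    X,
    y,
    train_sizes,
    cv_folds: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean train / cross-validation R^2 at each training-set size.

    For each size the first ``size`` rows of one seeded permutation are
    k-folded; the model from ``model_factory()`` is fitted on each fold's
    training part and scored on both parts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    sizes = np.asarray(train_sizes, dtype=int)
    if np.any(np.diff(sizes) <= 0):
        raise ValueError("train_sizes must be strictly increasing")
    if np.any(sizes < cv_folds):
        raise ValueError("every size must be >= cv_folds")
    if sizes.max() > X.shape[0]:
        raise ValueError("train size exceeds available rows")
    perm = np.random.default_rng(seed).permutation(X.shape[0])
    train_scores = np.empty(sizes.size)
    cv_scores = np.empty(sizes.size)
    for si, size in enumerate(sizes):
        sub = perm[:size]
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        tr_sc, cv_sc = [], []
        for tr, te in kf.split(sub):
            model = model_factory()
            model.fit(X[sub[tr]], y[sub[tr]])
            tr_sc.append(r2_score(y[sub[tr]], model.predict(X[sub[tr]])))
            cv_sc.append(r2_score(y[sub[te]], model.predict(X[sub[te]])))
        train_scores[si] = np.mean(tr_sc)
        cv_scores[si] = np.mean(cv_sc)
    return sizes, train_scores, cv_scores


@dataclass(frozen=True)
class PDCurve:
    feature: str
    grid: np.ndarray
    average: np.ndarray  # mean prediction at each grid value, m/s

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.average)):
            raise ValueError("averages must be finite")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({self.feature: self.grid, "U": self.average}).to_csv(
            path, index=False
        )


def partial_dependence(model, data: pd.DataFrame, feature: str, grid_size: int = 50) -> PDCurve:
    """Average prediction as ``feature`` sweeps its observed range with the
    other input held at its observed values."""
    if feature not in ("x", "y"):
        raise ValueError("feature must be 'x' or 'y'")
    if len(data) == 0:
        raise ValueError("empty data")
    grid = np.linspace(data[feature].min(), data[feature].max(), grid_size)
    X = data[["x", "y"]].to_numpy(dtype=float)
    col = 0 if feature == "x" else 1
    avg = np.empty(grid_size)
    for i, g in enumerate(grid):
        Xg = X.copy()
        Xg[:, col] = g
        avg[i] = float(np.mean(model.predict(Xg)))
    return PDCurve(feature=feature, grid=grid, average=avg)


def prediction_surface(
    model,
    grid_spec: GridSpec,
    domain: GridSpec | None = None,
) -> pd.DataFrame:
    """Model evaluated on the tensor node grid of ``grid_spec``.

    ``domain`` (default: the grid itself) bounds the training region; a grid
    extending beyond it is refused — the surrogate is an interpolant, not an
    extrapolator.
    """
    dom = domain or grid_spec
    if (
        grid_spec.x_min < dom.x_min
        or grid_spec.x_max > dom.x_max
        or grid_spec.y_min < dom.y_min
        or grid_spec.y_max > dom.y_max
    ):
        raise ValueError("surface grid extends outside the training domain")
    xs = np.linspace(grid_spec.x_min, grid_spec.x_max, grid_spec.nx)
    ys = np.linspace(grid_spec.y_min, grid_spec.y_max, grid_spec.ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    U = np.asarray(model.predict(pts), dtype=float)
    return pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "U": U})
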