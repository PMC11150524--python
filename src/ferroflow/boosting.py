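"""AdaBoost for regression (the AdaBoost.R2 scheme with linear loss).

Each round fits a base model to the (re)weighted training set, measures the
normalized per-row loss l_i = |e_i| / max_j |e_j|, forms the average loss
L_t = sum_i w_i l_i, the confidence ratio beta_t = L_t / (1 - L_t) and the
model weight ln(1/beta_t), then concentrates the sample weights on the rows
the round predicted worst: w_i <- w_i * beta_t^(1 - l_i), renormalized.
Predictions are combined either by confidence-weighted averaging (default,
matching the study's description) or by the weighted median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regressors import WEIGHT_AWARE_FAMILIES, make_base_learner

#: floor on beta when a round fits the training set (essentially) perfectly
_BETA_FLOOR = 1e-12


class BoostingError(RuntimeError):
    pass


@dataclass
class BoostEnsemble:
    """Fitted base models with per-round confidences.

    ``model_weights[t] = ln(1 / beta_t) > 0``.  ``weight_history`` keeps the
    sample-weight vector entering each round (diagnostic, small).
    """

    models: list
    avg_losses: list[float]
    betas: list[float]
    model_weights: list[float]
    family: str
    n_estimators: int
    mode: str = "weighted_average"
    weight_history: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.models)


def fit_adaboost(
    X,
    y,
    base_family: str,
    base_hyperparams: dict | None = None,
    n_estimators: int = 50,
    seed: int = 0,
    mode: str = "weighted_average",
    keep_weight_history: bool = False,
) -> BoostEnsemble:
    """Fit the sequential reweighted ensemble.

    Weight-aware families (trees) receive the sample weights natively; the
    others are fitted on a weighted bootstrap resample.  Stops early when a
    round's average loss reaches 0.5 (model discarded) or when a round fits
    perfectly (model kept with a capped weight).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_estimators < 1:
        raise ValueError("n_estimators must be >= 1")
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    w = np.full(n, 1.0 / n)

    models, avg_losses, betas, mweights, history = [], [], [], [], []
    for t in range(n_estimators):
        if keep_weight_history:
            history.append(w.copy())
        model = make_base_learner(
            base_family, base_hyperparams or {}, seed=int(rng.integers(2**31))
        )
        if base_family in WEIGHT_AWARE_FAMILIES:
            model.fit(X, y, sample_weight=w)
        else:
            idx = rng.choice(n, size=n, replace=True, p=w)
            model.fit(X[idx], y[idx])
        err = np.abs(model.predict(X) - y)
        denom = err.max()
        if denom <= 0.0:
            lbar = 0.0
        else:
            l = err / denom
            lbar = float(np.dot(w, l))
        if lbar >= 0.5:
            if t == 0:
                raise BoostingError(
                    f"base learner no better than random (average loss {lbar:.3f})"
                )
            break
        beta = max(lbar / (1.0 - lbar), _BETA_FLOOR)
        models.append(model)
        avg_losses.append(lbar)
        betas.append(beta)
        mweights.append(float(np.log(1.0 / beta)))
        if lbar < 1e-12:
            break  # perfect fit: nothing left to reweight
        w = w * beta ** (1.0 - l)
        w = w / w.sum()
    return BoostEnsemble(
        models=models,
        avg_losses=avg_losses,
        betas=betas,
        model_weights=mweights,
        family=base_family,
        n_estimators=n_estimators,
        mode=mode,
        weight_history=history,
    )


def _prediction_matrix(ensemble: BoostEnsemble, X) -> np.ndarray:
    """Stacked base predictions, shape (T, n)."""
    return np.stack([m.predict(X) for m in ensemble.models])


def _weighted_median(P: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-column weighted median: smallest prediction whose cumulative
    sorted weight reaches half the total."""
    order = np.argsort(P, axis=0, kind="stable")
    sorted_P = np.take_along_axis(P, order, axis=0)
    cum = np.cumsum(w[order], axis=0)
    pick = np.argmax(cum >= 0.5 * w.sum(), axis=0)
    return sorted_P[pick, np.arange(P.shape[1])]


def predict_ensemble(ensemble: BoostEnsemble, X, mode: str | None = None) -> np.ndarray:
    """Aggregate base predictions by confidence weights."""
    if len(ensemble) == 0:
        raise BoostingError("empty ensemble")
    mode = mode or ensemble.mode
    P = _prediction_matrix(ensemble, X)
    w = np.asarray(ensemble.model_weights)
    if mode == "weighted_average":
        return (w @ P) / w.sum()
    if mode == "weighted_median":
        return _weighted_median(P, w)
    raise ValueError(f"unknown aggregation mode {mode!r}")


def staged_scores(ensemble: BoostEnsemble, X, y, mode: str | None = None) -> np.ndarray:
    """R^2 of each prefix-ensemble (1..T models): the estimator-count curve."""
    from .evaluation import r2_score

    if len(ensemble) == 0:
        raise BoostingError("empty ensemble")
    mode = mode or ensemble.mode
    P = _prediction_matrix(ensemble, X)
    w = np.asarray(ensemble.model_weights)
    y = np.asarray(y, dtype=float)
    scores = np.empty(len(ensemble))
    if mode == "weighted_average":
        num = np.cumsum(w[:, None] * P, axis=0)
        den = np.cumsum(w)
        for t in range(len(ensemble)):
            scores[t] = r2_score(y, num[t] / den[t])
    else:
        for t in range(len(ensemble)):
            scores[t] = r2_score(y, _weighted_median(P[: t + 1], w[: t + 1]))
    return scores
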