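"""AdaBoost.R2: reweighting loop, aggregation rules, staged scores."""

import numpy as np
import pytest

from ferroflow.boosting import (
    BoostEnsemble,
    BoostingError,
    fit_adaboost,
    predict_ensemble,
    staged_scores,
)
from ferroflow.regressors import fit_tree, predict_tree


class _ConstantModel:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(np.atleast_2d(X).shape[0], self.value)


def _manual_ensemble(values, weights, mode="weighted_average"):
    return BoostEnsemble(
        models=[_ConstantModel(v) for v in values],
        avg_losses=[0.1] * len(values),
        betas=[0.1] * len(values),
        model_weights=list(weights),
        family="tree",
        n_estimators=len(values),
        mode=mode,
    )


# --- fitting ---------------------------------------------------------------


def _toy_data():
    # a depth-1 stump leaves errors (0,0,0,1/6,1/6,1/3): normalized losses
    # (0,0,0,.5,.5,1), average 1/3 < 1/2, so boosting proceeds past round 1
    X = np.arange(6, dtype=float)[:, None]
    y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.5])
    return X, y


def test_single_estimator_equals_base_model():
    X, y = _toy_data()
    ens = fit_adaboost(X, y, "tree", {"max_depth": 2}, n_estimators=1, seed=0)
    base = fit_tree(X, y, max_depth=2, sample_weight=np.full(6, 1 / 6))
    np.testing.assert_allclose(predict_ensemble(ens, X), predict_tree(base, X))


def test_perfect_first_round_stops_training():
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array([0.0, 0.0, 1.0, 1.0])  # exactly realizable by a stump
    ens = fit_adaboost(X, y, "tree", {"max_depth": 1}, n_estimators=10, seed=0)
    assert len(ens) == 1
    np.testing.assert_array_equal(predict_ensemble(ens, X), y)


def test_round_one_weight_update_matches_hand_execution():
    """Re-execute the update rule w_i * beta^(1 - l_i) independently and
    compare with the weights entering round 2."""
    X, y = _toy_data()
    ens = fit_adaboost(
        X, y, "tree", {"max_depth": 1}, n_estimators=2, seed=0, keep_weight_history=True
    )
    assert len(ens.weight_history) >= 2
    w0 = ens.weight_history[0]
    np.testing.assert_allclose(w0, 1.0 / 6.0)
    stump = fit_tree(X, y, max_depth=1, sample_weight=w0)
    err = np.abs(predict_tree(stump, X) - y)
    l = err / err.max()
    lbar = float(w0 @ l)
    beta = lbar / (1.0 - lbar)
    w1 = w0 * beta ** (1.0 - l)
    w1 = w1 / w1.sum()
    assert ens.avg_losses[0] == pytest.approx(lbar, abs=1e-12)
    assert ens.betas[0] == pytest.approx(beta, abs=1e-12)
    np.testing.assert_allclose(ens.weight_history[1], w1, atol=1e-10)


def test_sample_weights_stay_probability_vectors():
    rng = np.random.default_rng(0)
    X = rng.uniform(size=(40, 2))
    y = rng.normal(size=40)
    ens = fit_adaboost(
        X, y, "tree", {"max_depth": 2}, n_estimators=8, seed=1, keep_weight_history=True
    )
    for w in ens.weight_history:
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_harder_rows_gain_relative_weight():
    X, y = _toy_data()
    ens = fit_adaboost(
        X, y, "tree", {"max_depth": 1}, n_estimators=2, seed=0, keep_weight_history=True
    )
    w0, w1 = ens.weight_history[0], ens.weight_history[1]
    stump_pred = ens.models[0].predict(X)
    l = np.abs(stump_pred - y)
    l = l / l.max()
    ratio = w1 / w0
    hardest, easiest = np.argmax(l), np.argmin(l)
    assert ratio[hardest] > ratio[easiest]


def test_useless_first_learner_raises():
    # a forced single-leaf tree predicts the mean of balanced +-1 targets:
    # every normalized loss is 1, so the average loss is 1 >= 0.5
    rng = np.random.default_rng(2)
    X = rng.uniform(size=(30, 2))
    y = np.tile([1.0, -1.0], 15)
    with pytest.raises(BoostingError, match="random"):
        fit_adaboost(X, y, "tree", {"max_depth": 1, "min_samples_leaf": 30}, n_estimators=3)


def test_bootstrap_families_fit():
    rng = np.random.default_rng(3)
    X = rng.uniform(size=(60, 2))
    y = X[:, 0] + 0.1 * rng.normal(size=60)
    ens = fit_adaboost(X, y, "knn", {"k": 2}, n_estimators=3, seed=0)
    assert 1 <= len(ens) <= 3
    preds = predict_ensemble(ens, X)
    assert np.all(np.isfinite(preds))


# --- aggregation -----------------------------------------------------------


def test_identical_models_match_single_model_in_both_modes():
    ens = _manual_ensemble([2.5, 2.5, 2.5], [0.7, 1.3, 0.2])
    X = np.zeros((4, 2))
    np.testing.assert_allclose(predict_ensemble(ens, X, "weighted_average"), 2.5)
    np.testing.assert_allclose(predict_ensemble(ens, X, "weighted_median"), 2.5)


def test_equal_weight_aggregation_closed_forms():
    ens = _manual_ensemble([1.0, 2.0, 10.0], [1.0, 1.0, 1.0])
    X = np.zeros((1, 2))
    assert predict_ensemble(ens, X, "weighted_average")[0] == pytest.approx(13.0 / 3.0)
    assert predict_ensemble(ens, X, "weighted_median")[0] == 2.0


@pytest.mark.parametrize("seed", range(5))
def test_weighted_median_matches_cumulative_scan(seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=7)
    weights = rng.uniform(0.1, 2.0, size=7)
    ens = _manual_ensemble(values, weights)
    got = predict_ensemble(ens, np.zeros((1, 2)), "weighted_median")[0]
    order = np.argsort(values)
    cum = np.cumsum(weights[order])
    expected = values[order][np.searchsorted(cum, 0.5 * weights.sum())]
    assert got == expected


def test_weighted_median_is_monotone_in_any_prediction():
    values = [1.0, 3.0, 5.0]
    weights = [1.0, 1.0, 1.0]
    base = predict_ensemble(_manual_ensemble(values, weights), np.zeros((1, 2)), "weighted_median")[0]
    bumped = predict_ensemble(
        _manual_ensemble([1.0, 4.0, 5.0], weights), np.zeros((1, 2)), "weighted_median"
    )[0]
    assert bumped >= base


def test_empty_ensemble_rejected():
    ens = _manual_ensemble([], [])
    with pytest.raises(BoostingError):
        predict_ensemble(ens, np.zeros((1, 2)))


# --- staged scores ---------------------------------------------------------


def test_staged_scores_endpoints():
    rng = np.random.default_rng(4)
    X = rng.uniform(size=(80, 2))
    y = X[:, 0] ** 2 + X[:, 1] + 0.05 * rng.normal(size=80)
    ens = fit_adaboost(X, y, "tree", {"max_depth": 3}, n_estimators=6, seed=0)
    scores = staged_scores(ens, X, y)
    assert scores.size == len(ens)
    from ferroflow.evaluation import r2_score

    full = r2_score(y, predict_ensemble(ens, X))
    first = r2_score(y, ens.models[0].predict(X))
    assert scores[-1] == pytest.approx(full, abs=1e-12)
    assert scores[0] == pytest.approx(first, abs=1e-12)


def test_cross_check_against_reference_boosting_library():
    """Independent oracle: sklearn's AdaBoost.R2 (weighted-median) should
    land within a few points of R^2 of this implementation on smooth data."""
    from sklearn.ensemble import AdaBoostRegressor
    from sklearn.tree import DecisionTreeRegressor

    rng = np.random.default_rng(5)
    X = rng.uniform(-1, 1, size=(300, 2))
    y = np.sin(2 * X[:, 0]) + X[:, 1] ** 2 + 0.05 * rng.normal(size=300)
    ours = fit_adaboost(X, y, "tree", {"max_depth": 4}, n_estimators=20, seed=0)
    ref = AdaBoostRegressor(
        estimator=DecisionTreeRegressor(max_depth=4), n_estimators=20, random_state=0
    ).fit(X, y)
    from ferroflow.evaluation import r2_score

    r2_ours = r2_score(y, predict_ensemble(ours, X, "weighted_median"))
    r2_ref = r2_score(y, ref.predict(X))
    assert abs(r2_ours - r2_ref) <= 0.05
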