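"""Base regressors: CART splits, KNN neighbor search, MLP forward/training."""

import numpy as np
import pytest

from ferroflow.regressors import (
    KNNConfig,
    KNNRegressorModel,
    MLPConfig,
    MLPModel,
    fit_mlp,
    fit_tree,
    knn_predict,
    make_base_learner,
    mlp_forward,
    predict_tree,
)


# --- CART ------------------------------------------------------------------


def brute_force_best_split(X, y):
    """Exhaustive scan over features and midpoint thresholds; returns the
    minimum achievable sum of child squared errors."""
    best = np.inf
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        for thr in 0.5 * (vals[:-1] + vals[1:]):
            left = y[X[:, j] <= thr]
            right = y[X[:, j] > thr]
            sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
            best = min(best, sse)
    return best


def test_depth_zero_predicts_global_mean():
    X = np.array([[0.0], [1.0], [2.0]])
    y = np.array([1.0, 2.0, 6.0])
    model = fit_tree(X, y, max_depth=0)
    np.testing.assert_allclose(predict_tree(model, X), 3.0)


def test_step_function_split_threshold_and_zero_sse():
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array([0.0, 0.0, 1.0, 1.0])
    model = fit_tree(X, y, max_depth=1)
    np.testing.assert_array_equal(predict_tree(model, X), y)
    thr = model.estimator.tree_.threshold[0]
    assert 1.0 < thr < 2.0


@pytest.mark.parametrize("seed", range(5))
def test_root_split_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(50, 2))
    y = rng.normal(size=50)
    model = fit_tree(X, y, max_depth=1)
    pred = predict_tree(model, X)
    sse = ((y - pred) ** 2).sum()
    assert sse == pytest.approx(brute_force_best_split(X, y), rel=1e-9)


def test_prediction_is_piecewise_constant_on_leaf_cells():
    rng = np.random.default_rng(1)
    X = rng.uniform(size=(60, 2))
    y = rng.normal(size=60)
    model = fit_tree(X, y, max_depth=3)
    queries = rng.uniform(size=(200, 2))
    leaves = model.estimator.apply(queries)
    preds = predict_tree(model, queries)
    for leaf in np.unique(leaves):
        cell = preds[leaves == leaf]
        assert np.all(cell == cell[0])
    # leaf values are the means of the training targets routed there
    train_leaves = model.estimator.apply(X)
    for leaf in np.unique(train_leaves):
        assert predict_tree(model, X[train_leaves == leaf][:1])[0] == pytest.approx(
            y[train_leaves == leaf].mean()
        )


def test_training_sse_nonincreasing_in_depth():
    rng = np.random.default_rng(2)
    X = rng.uniform(size=(80, 2))
    y = rng.normal(size=80)
    sses = []
    for depth in (1, 2, 4, 8):
        model = fit_tree(X, y, max_depth=depth)
        sses.append(((y - predict_tree(model, X)) ** 2).sum())
    assert np.all(np.diff(sses) <= 1e-12)


def test_tree_feature_mismatch_and_empty_input():
    with pytest.raises(ValueError):
        fit_tree(np.empty((0, 2)), np.empty(0), max_depth=2)
    model = fit_tree(np.array([[0.0, 1.0]]), np.array([1.0]), max_depth=1)
    with pytest.raises(ValueError):
        predict_tree(model, np.array([[1.0, 2.0, 3.0]]))


# --- KNN -------------------------------------------------------------------


def test_knn_345_triangle_nearest():
    train_X = np.array([[3.0, 4.0], [6.0, 8.0]])
    train_y = np.array([1.0, 2.0])
    # (0,0) is 5 from the first point, 10 from the second
    assert knn_predict(train_X, train_y, np.array([0.0, 0.0]), KNNConfig(k=1)) == 1.0


def test_knn_query_on_training_point():
    rng = np.random.default_rng(0)
    X = rng.uniform(size=(20, 2))
    y = rng.normal(size=20)
    assert knn_predict(X, y, X[7], KNNConfig(k=1)) == y[7]


def test_knn_tie_breaks_to_lowest_index():
    X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0]])  # first two equidistant from origin
    y = np.array([10.0, 20.0, 30.0])
    assert knn_predict(X, y, np.array([0.0, 0.0]), KNNConfig(k=1)) == 10.0


def test_knn_with_k_equal_n_predicts_global_mean():
    rng = np.random.default_rng(3)
    X = rng.uniform(size=(15, 2))
    y = rng.normal(size=15)
    pred = knn_predict(X, y, np.array([0.3, 0.7]), KNNConfig(k=15))
    assert pred == pytest.approx(y.mean())


def test_knn_matches_brute_force_full_sort():
    rng = np.random.default_rng(4)
    X = rng.uniform(size=(100, 2))
    y = rng.normal(size=100)
    queries = rng.uniform(size=(25, 2))
    preds = knn_predict(X, y, queries, KNNConfig(k=2))
    for q, p in zip(queries, preds):
        order = np.argsort(np.linalg.norm(X - q, axis=1), kind="stable")
        assert p == pytest.approx(y[order[:2]].mean(), rel=1e-12)


def test_knn_wrapper_agrees_with_reference_predictor():
    rng = np.random.default_rng(5)
    X = rng.uniform(size=(200, 2))
    y = rng.normal(size=200)
    queries = rng.uniform(size=(50, 2))
    wrapper = KNNRegressorModel(k=2).fit(X, y)
    np.testing.assert_allclose(
        wrapper.predict(queries), knn_predict(X, y, queries, KNNConfig(k=2)), rtol=1e-12
    )


def test_knn_empty_training_set_rejected():
    with pytest.raises(ValueError):
        knn_predict(np.empty((0, 2)), np.empty(0), np.array([0.0, 0.0]), KNNConfig(k=1))


# --- MLP -------------------------------------------------------------------


def test_forward_zero_weights_returns_output_bias():
    model = MLPModel(
        weights=[np.zeros((2, 3)), np.zeros((3, 1))],
        biases=[np.zeros(3), np.array([1.5])],
        activation="relu",
    )
    assert mlp_forward(model, np.array([0.3, -0.8])) == pytest.approx(1.5)


def test_forward_identity_activation_collapses_to_affine():
    rng = np.random.default_rng(0)
    W1, b1 = rng.normal(size=(2, 4)), rng.normal(size=4)
    W2, b2 = rng.normal(size=(4, 1)), rng.normal(size=1)
    model = MLPModel(weights=[W1, W2], biases=[b1, b2], activation="identity")
    x = rng.normal(size=(10, 2))
    expected = (x @ W1 + b1) @ W2 + b2
    np.testing.assert_allclose(mlp_forward(model, x), expected[:, 0], rtol=1e-12)


def test_forward_hand_traced_relu_network():
    # 2-2-1, all weights 1, biases 0, input (1, -1):
    # hidden pre-activation (0, 0) -> ReLU (0, 0) -> output 0
    model = MLPModel(
        weights=[np.ones((2, 2)), np.ones((2, 1))],
        biases=[np.zeros(2), np.zeros(1)],
        activation="relu",
    )
    assert mlp_forward(model, np.array([1.0, -1.0])) == 0.0


def test_forward_dimension_mismatch_rejected():
    model = MLPModel(
        weights=[np.ones((2, 2)), np.ones((2, 1))],
        biases=[np.zeros(2), np.zeros(1)],
    )
    with pytest.raises(ValueError):
        mlp_forward(model, np.ones(3))
    with pytest.raises(ValueError):
        MLPModel(weights=[np.ones((2, 3)), np.ones((4, 1))], biases=[np.zeros(3), np.zeros(1)])


def test_fit_mlp_recovers_affine_map():
    rng = np.random.default_rng(6)
    X = rng.uniform(-1, 1, size=(400, 2))
    y = 2.0 * X[:, 0] - 0.5 * X[:, 1] + 0.3 + rng.normal(0, 0.01, size=400)
    cfg = MLPConfig(hidden_sizes=(16,), max_iter=300, seed=0)
    model = fit_mlp(X, y, cfg)
    X_new = rng.uniform(-1, 1, size=(200, 2))
    y_new = 2.0 * X_new[:, 0] - 0.5 * X_new[:, 1] + 0.3
    pred = mlp_forward(model, X_new)
    ss_res = ((y_new - pred) ** 2).sum()
    ss_tot = ((y_new - y_new.mean()) ** 2).sum()
    assert 1.0 - ss_res / ss_tot >= 0.99


def test_fit_mlp_constant_target():
    X = np.random.default_rng(7).uniform(size=(50, 2))
    y = np.full(50, 0.7)
    model = fit_mlp(X, y, MLPConfig(hidden_sizes=(8,), max_iter=200, seed=0))
    np.testing.assert_allclose(mlp_forward(model, X), 0.7, atol=1e-3)


def test_fit_mlp_deterministic_given_seed():
    rng = np.random.default_rng(8)
    X = rng.uniform(size=(100, 2))
    y = np.sin(X[:, 0]) + X[:, 1]
    cfg = MLPConfig(hidden_sizes=(8,), max_iter=100, seed=3)
    m1 = fit_mlp(X, y, cfg)
    m2 = fit_mlp(X, y, cfg)
    for W1, W2 in zip(m1.weights, m2.weights):
        np.testing.assert_array_equal(W1, W2)


def test_make_base_learner_families():
    for family in ("tree", "knn", "mlp"):
        model = make_base_learner(family, {}, seed=0)
        assert hasattr(model, "fit") and hasattr(model, "predict")
    with pytest.raises(ValueError):
        make_base_learner("svm", {})
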