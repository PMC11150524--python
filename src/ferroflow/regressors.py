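"""Base regressors of the surrogate: CART tree, K-nearest-neighbors, MLP.

Training of the tree and the network is delegated to scikit-learn; this
module fixes the conventions the ensemble relies on (variance-reduction
splitting with midpoint thresholds, true Euclidean KNN with lowest-index
tie-breaks, ReLU feedforward network trained on mean squared error) and
exposes the fitted parameters in plain dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.tree import DecisionTreeRegressor


# ---------------------------------------------------------------------------
# CART regression tree
# ---------------------------------------------------------------------------


@dataclass
class TreeModel:
    """A fitted CART regression tree (leaf values = routed target means)."""

    estimator: DecisionTreeRegressor | None  # None for a depth-0 stump
    constant: float | None
    max_depth: int
    n_features: int

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        if self.estimator is None:
            return np.full(X.shape[0], self.constant)
        return self.estimator.predict(X)


def fit_tree(
    X, y, max_depth: int, min_samples_leaf: int = 1, sample_weight=None, seed: int = 0
) -> TreeModel:
    """Greedy binary CART minimizing summed squared error of child means.

    ``max_depth = 0`` degenerates to a single leaf predicting the
    (weighted) global mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    if max_depth == 0:
        mean = float(np.average(y, weights=sample_weight))
        return TreeModel(estimator=None, constant=mean, max_depth=0, n_features=X.shape[1])
    est = DecisionTreeRegressor(
        criterion="squared_error",
        max_depth=max_depth,
        min_samples_leaf=min_samples_leaf,
        random_state=seed,  # split tie-breaks; grid data has many ties
    )
    est.fit(X, y, sample_weight=sample_weight)
    return TreeModel(estimator=est, constant=None, max_depth=max_depth, n_features=X.shape[1])


def predict_tree(model: TreeModel, X) -> np.ndarray:
    """Route rows down the tree (left if value <= threshold); leaf means out."""
    return model.predict(X)


# ---------------------------------------------------------------------------
# K-nearest neighbors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KNNConfig:
    k: int = 2

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def knn_predict(train_X, train_y, query, cfg: KNNConfig) -> np.ndarray:
    """Mean target of the k nearest training rows by Euclidean distance
    D(X, Y) = sqrt(sum_i (X_i - Y_i)^2); distance ties break toward the
    lowest training-row index (stable sort).
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    train_y = np.asarray(train_y, dtype=float)
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    if cfg.k > train_X.shape[0]:
        raise ValueError("k exceeds training size")
    Q = np.asarray(query, dtype=float)
    single = Q.ndim == 1
    Q = np.atleast_2d(Q)
    d = np.sqrt(((Q[:, None, :] - train_X[None, :, :]) ** 2).sum(axis=2))
    order = np.argsort(d, axis=1, kind="stable")[:, : cfg.k]
    out = train_y[order].mean(axis=1)
    return float(out[0]) if single else out


class KNNRegressorModel:
    """KNN estimator used inside the boosting loop (tree-based neighbor
    search for speed; agrees with :func:`knn_predict` on tie-free data)."""

    def __init__(self, k: int = 2):
        self.k = k
        self._est = KNeighborsRegressor(n_neighbors=k)

    def fit(self, X, y, sample_weight=None):
        self._est.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
        return self

    def predict(self, X) -> np.ndarray:
        return self._est.predict(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# multilayer perceptron
# ---------------------------------------------------------------------------

_ACTIVATIONS = {
    "relu": lambda z: np.maximum(z, 0.0),
    "identity": lambda z: z,
    "tanh": np.tanh,
    "logistic": lambda z: 1.0 / (1.0 + np.exp(-z)),
}


@dataclass(frozen=True)
class MLPConfig:
    hidden_sizes: tuple[int, ...] = (66, 29)
    activation: str = "relu"
    solver: str = "lbfgs"
    learning_rate: float = 1e-3  # eta; used by the sgd/adam solvers
    max_iter: int = 400
    seed: int = 0


@dataclass
class MLPModel:
    """Feedforward network parameters: y = W_L f(... f(W_1 x + b_1) ...) + b_L
    with linear output (regression)."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activation: str = "relu"

    def __post_init__(self) -> None:
        for W, Wn in zip(self.weights[:-1], self.weights[1:]):
            if W.shape[1] != Wn.shape[0]:
                raise ValueError("adjacent layer dimensions not conformable")


def mlp_forward(model: MLPModel, x) -> np.ndarray:
    """Forward pass: alternating affine maps and activations, linear output."""
    f = _ACTIVATIONS[model.activation]
    a = np.asarray(x, dtype=float)
    single = a.ndim == 1
    a = np.atleast_2d(a)
    if a.shape[1] != model.weights[0].shape[0]:
        raise ValueError(
            f"input dimension {a.shape[1]} does not match first layer "
            f"({model.weights[0].shape[0]})"
        )
    for W, b in zip(model.weights[:-1], model.biases[:-1]):
        a = f(a @ W + b)
    a = a @ model.weights[-1] + model.biases[-1]
    out = a[:, 0] if a.shape[1] == 1 else a
    return float(out[0]) if single and out.ndim == 1 else out


class MLPRegressorModel:
    """MLP estimator used inside the boosting loop (scikit-learn training,
    seeded and deterministic for the quasi-Newton solver)."""

    def __init__(self, cfg: MLPConfig):
        self.cfg = cfg
        self._est = MLPRegressor(
            hidden_layer_sizes=cfg.hidden_sizes,
            activation=cfg.activation,
            solver=cfg.solver,
            learning_rate_init=cfg.learning_rate,
            max_iter=cfg.max_iter,
            random_state=cfg.seed,
        )

    def fit(self, X, y, sample_weight=None):
        self._est.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
        return self

    def predict(self, X) -> np.ndarray:
        return self._est.predict(np.asarray(X, dtype=float))

    def to_model(self) -> MLPModel:
        return MLPModel(
            weights=[W.copy() for W in self._est.coefs_],
            biases=[b.copy() for b in self._est.intercepts_],
            activation=self.cfg.activation,
        )


def fit_mlp(X, y, cfg: MLPConfig) -> MLPModel:
    """Train the network on MSE by gradient-based minimization; seeded.

    Returns the fitted parameters as a plain :class:`MLPModel` so the
    forward pass is reproducible without the training machinery.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    wrapper = MLPRegressorModel(cfg).fit(X, y)
    model = wrapper.to_model()
    if not all(np.all(np.isfinite(W)) for W in model.weights):
        raise RuntimeError("training produced non-finite parameters")
    return model


# ---------------------------------------------------------------------------
# factory used by the ensemble and the tuner
# ---------------------------------------------------------------------------


class TreeRegressorModel:
    """Weight-aware CART wrapper with the ensemble's fit/predict surface."""

    def __init__(self, max_depth: int = 8, min_samples_leaf: int = 1, seed: int = 0):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed
        self._model: TreeModel | None = None

    def fit(self, X, y, sample_weight=None):
        self._model = fit_tree(
            X,
            y,
            self.max_depth,
            self.min_samples_leaf,
            sample_weight=sample_weight,
            seed=self.seed,
        )
        return self

    def predict(self, X) -> np.ndarray:
        return self._model.predict(X)


#: base families that accept per-row weights natively (no bootstrap needed)
WEIGHT_AWARE_FAMILIES = {"tree"}


def make_base_learner(family: str, hyperparams: dict, seed: int = 0):
    """Instantiate an unfitted base learner for the given family."""
    hp = dict(hyperparams)
    if family == "tree":
        return TreeRegressorModel(
            max_depth=int(hp.get("max_depth", 8)),
            min_samples_leaf=int(hp.get("min_samples_leaf", 1)),
            seed=int(hp.get("seed", seed)),
        )
    if family == "knn":
        return KNNRegressorModel(k=int(hp.get("k", 2)))
    if family == "mlp":
        cfg = MLPConfig(
            hidden_sizes=tuple(int(h) for h in hp.get("hidden_sizes", (66, 29))),
            activation=hp.get("activation", "relu"),
            solver=hp.get("solver", "lbfgs"),
            learning_rate=float(hp.get("learning_rate", 1e-3)),
            max_iter=int(hp.get("max_iter", 400)),
            seed=int(hp.get("seed", seed)),
        )
        return MLPRegressorModel(cfg)
    raise ValueError(f"unknown base family {family!r}")
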