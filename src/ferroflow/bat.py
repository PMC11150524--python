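"""BAT metaheuristic for hyperparameter search.

A swarm of candidate hyperparameter vectors ("bats") moves through the
search box under the echolocation-inspired update rules

    f_i     = f_min + (f_max - f_min) * beta,      beta ~ U(0,1) per dim
    v_i     = v_i + (Theta_i - Theta_best) * f_i
    Theta_i = Theta_i + v_i

with positions clipped to the bounds and integer dimensions rounded after
every move.  The three rules alone are purely explorative (the recursion is
linearly unstable around the best position), so by default the swarm also
carries the classical loudness/pulse-rate mechanics: with probability
1 - pulse_rate a bat performs a small random walk around the best-known
position instead of the global move, and worse moves are accepted with
probability equal to the loudness.  Setting ``use_loudness=False`` gives
the bare three-rule variant.  Velocities are clamped to one box width per
dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .boosting import fit_adaboost, predict_ensemble
from .regressors import make_base_learner


class TuningError(RuntimeError):
    pass


@dataclass(frozen=True)
class Dimension:
    name: str
    kind: str  # "integer" | "real"
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.kind not in ("integer", "real"):
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if not self.low < self.high:
            raise ValueError(f"dimension {self.name!r}: low must be < high")


@dataclass(frozen=True)
class SearchSpace:
    """Flat list of scalar dimensions.  Tuple-valued hyperparameters (e.g.
    hidden layer sizes) are flattened into one integer dimension per entry
    via :meth:`add_integer_tuple` naming them ``name_0, name_1, ...``."""

    dims: tuple[Dimension, ...]
    tuple_stems: tuple[str, ...] = ()

    @classmethod
    def create(cls, entries) -> "SearchSpace":
        """entries: iterable of (name, kind, low, high) with kind optionally
        'integer_tuple:<len>' to expand a tuple dimension."""
        dims: list[Dimension] = []
        stems: list[str] = []
        for name, kind, low, high in entries:
            if kind.startswith("integer_tuple"):
                length = int(kind.split(":")[1])
                dims.extend(
                    Dimension(f"{name}_{i}", "integer", low, high) for i in range(length)
                )
                stems.append(name)
            else:
                dims.append(Dimension(name, kind, low, high))
        return cls(dims=tuple(dims), tuple_stems=tuple(stems))

    @property
    def ndim(self) -> int:
        return len(self.dims)

    @property
    def lows(self) -> np.ndarray:
        return np.array([d.low for d in self.dims])

    @property
    def highs(self) -> np.ndarray:
        return np.array([d.high for d in self.dims])

    @property
    def integer_mask(self) -> np.ndarray:
        return np.array([d.kind == "integer" for d in self.dims])

    def clip_round(self, position: np.ndarray) -> np.ndarray:
        pos = np.clip(position, self.lows, self.highs)
        mask = self.integer_mask
        pos = np.where(mask, np.rint(pos), pos)
        return pos

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return self.clip_round(rng.uniform(self.lows, self.highs))

    def decode(self, position: np.ndarray) -> dict:
        """Position vector -> hyperparameter dict (tuple dims regrouped)."""
        out: dict = {}
        tuples: dict[str, list[tuple[int, float]]] = {}
        for d, val in zip(self.dims, position):
            v = int(round(val)) if d.kind == "integer" else float(val)
            stem, _, idx = d.name.rpartition("_")
            if stem in self.tuple_stems and idx.isdigit():
                tuples.setdefault(stem, []).append((int(idx), v))
            else:
                out[d.name] = v
        for stem, items in tuples.items():
            out[stem] = tuple(v for _, v in sorted(items))
        return out


@dataclass(frozen=True)
class SwarmConfig:
    n_bats: int = 15
    n_iterations: int = 30
    f_min: float = 0.0
    f_max: float = 1.0
    seed: int = 0
    use_loudness: bool = True  # classical A / r mechanics
    loudness: float = 0.9
    pulse_rate: float = 0.5
    local_step: float = 0.05

    def __post_init__(self) -> None:
        if self.n_bats < 2:
            raise ValueError("n_bats must be >= 2")
        if not self.f_min < self.f_max:
            raise ValueError("f_min must be < f_max")


@dataclass
class BatState:
    position: np.ndarray
    velocity: np.ndarray
    frequency: np.ndarray
    fitness: float = -np.inf


def bat_step(
    state: BatState,
    best_position: np.ndarray,
    space: SearchSpace,
    cfg: SwarmConfig,
    rng: np.random.Generator,
) -> BatState:
    """One move of a single bat: frequency, velocity, position — in order."""
    beta = rng.uniform(size=space.ndim)
    freq = cfg.f_min + (cfg.f_max - cfg.f_min) * beta
    vel = state.velocity + (state.position - best_position) * freq
    width = space.highs - space.lows
    vel = np.clip(vel, -width, width)
    pos = space.clip_round(state.position + vel)
    return BatState(position=pos, velocity=vel, frequency=freq, fitness=-np.inf)


def evaluate_fitness(theta: dict, objective_spec: dict, data, seed: int) -> float:
    """k-fold cross-validated R^2 of the configured model at hyperparameters
    ``theta``; deterministic given ``seed``.  Fitting failures yield -inf.

    objective_spec keys: ``family`` ('tree'|'knn'|'mlp'), optional
    ``base_hyperparams`` merged under theta, optional ``n_estimators`` to
    boost the base model, optional ``cv_folds`` (default 3).
    """
    from sklearn.model_selection import KFold

    X, y = data
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    family = objective_spec["family"]
    hp = {**objective_spec.get("base_hyperparams", {}), **theta}
    n_estimators = objective_spec.get("n_estimators")
    folds = int(objective_spec.get("cv_folds", 3))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    try:
        for tr, te in kf.split(X):
            if n_estimators:
                ens = fit_adaboost(
                    X[tr], y[tr], family, hp, n_estimators=int(n_estimators), seed=seed
                )
                pred = predict_ensemble(ens, X[te])
            else:
                model = make_base_learner(family, hp, seed=seed)
                model.fit(X[tr], y[tr])
                pred = model.predict(X[te])
            ss_tot = float(np.sum((y[te] - y[te].mean()) ** 2))
            if ss_tot <= 1e-24 * max(1.0, float(np.sum(y[te] ** 2))):
                scores.append(0.0)
            else:
                scores.append(1.0 - float(np.sum((y[te] - pred) ** 2)) / ss_tot)
    except Exception:
        return -np.inf
    return float(np.mean(scores))


@dataclass
class TuneResult:
    best_position: np.ndarray
    best_theta: dict
    best_fitness: float
    trace: np.ndarray  # best-so-far fitness, one entry per iteration


def tune(space: SearchSpace, cfg: SwarmConfig, objective) -> TuneResult:
    """Run the swarm; returns the best-ever position and the monotone
    best-so-far trace.  ``objective(position) -> float`` (higher is better).
    """
    rng = np.random.default_rng(cfg.seed)
    bats = []
    for _ in range(cfg.n_bats):
        pos = space.sample(rng)
        bats.append(
            BatState(
                position=pos,
                velocity=np.zeros(space.ndim),
                frequency=np.zeros(space.ndim),
                fitness=float(objective(pos)),
            )
        )
    finite = [b for b in bats if np.isfinite(b.fitness)]
    if not finite:
        raise TuningError("all initial evaluations failed")
    best = max(bats, key=lambda b: b.fitness)
    best_pos, best_fit = best.position.copy(), best.fitness
    loudness = cfg.loudness

    trace = []
    for _ in range(cfg.n_iterations):
        for i, bat in enumerate(bats):
            new = bat_step(bat, best_pos, space, cfg, rng)
            if cfg.use_loudness and rng.uniform() > cfg.pulse_rate:
                width = space.highs - space.lows
                local = best_pos + cfg.local_step * loudness * rng.normal(size=space.ndim) * width
                new = replace(new, position=space.clip_round(local))
            new.fitness = float(objective(new.position))
            accept = np.isfinite(new.fitness) and (
                not cfg.use_loudness
                or new.fitness > bat.fitness
                or rng.uniform() < loudness
            )
            if accept:
                bats[i] = new
            if np.isfinite(new.fitness) and new.fitness > best_fit:
                best_fit = new.fitness
                best_pos = new.position.copy()
        trace.append(best_fit)
    if not np.isfinite(best_fit):
        raise TuningError("no successful evaluation")
    return TuneResult(
        best_position=best_pos,
        best_theta=space.decode(best_pos),
        best_fitness=best_fit,
        trace=np.asarray(trace),
    )
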