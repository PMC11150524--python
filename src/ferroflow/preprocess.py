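"""Data cleansing for the velocity table: outlier screening, scaling, split.

The chain mirrors standard surrogate-modelling practice: isolation-forest
anomaly scores flag rows to drop, min-max normalization maps the remaining
columns to [0, 1] (fitted on the training split only), and a seeded uniform
80/20 split separates train and test rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest


@dataclass(frozen=True)
class IsolationForestConfig:
    n_trees: int = 100
    subsample_size: int = 256  # psi
    score_threshold: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.subsample_size < 2:
            raise ValueError("subsample_size must be >= 2")
        if not 0.0 < self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be in (0, 1]")


def path_length_normalizer(n: int) -> float:
    """c(n) = 2 H(n-1) - 2 (n-1)/n, the mean unsuccessful-search path length
    of a binary search tree over n points (exact harmonic number).

    Normalizes isolation-tree path lengths: the anomaly score of a point is
    s = 2^(-E[h] / c(psi)).  c(2) = 1 exactly.
    """
    if n < 2:
        return 0.0
    harmonic = float(np.sum(1.0 / np.arange(1, n)))
    return 2.0 * harmonic - 2.0 * (n - 1) / n


def isolation_scores(table: pd.DataFrame, cfg: IsolationForestConfig) -> np.ndarray:
    """Per-row anomaly scores s(x) = 2^(-E[h(x)]/c(psi)), in (0, 1].

    Higher means more anomalous.  Deterministic given ``cfg.seed``.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to score")
    if cfg.subsample_size > len(table):
        raise ValueError(
            f"subsample_size {cfg.subsample_size} exceeds table size {len(table)}"
        )
    X = table.to_numpy(dtype=float)
    forest = IsolationForest(
        n_estimators=cfg.n_trees,
        max_samples=cfg.subsample_size,
        random_state=cfg.seed,
    ).fit(X)
    # sklearn's score_samples returns the negated canonical anomaly score
    return -forest.score_samples(X)


def remove_outliers(
    table: pd.DataFrame, cfg: IsolationForestConfig
) -> tuple[pd.DataFrame, np.ndarray]:
    """Drop rows scoring above the threshold; row order preserved.

    Returns the kept table (original index retained) and the removed row
    positions.  Raises if the threshold would remove every row.
    """
    scores = isolation_scores(table, cfg)
    removed = np.flatnonzero(scores > cfg.score_threshold)
    if removed.size == len(table):
        raise ValueError("score_threshold removed every row")
    kept = table.iloc[np.flatnonzero(scores <= cfg.score_threshold)]
    return kept, removed


# ---------------------------------------------------------------------------
# min-max scaling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScalerParams:
    """Per-column minima and maxima, in the column's own units."""

    minimum: dict[str, float]
    maximum: dict[str, float]

    def to_dict(self) -> dict:
        return {"minimum": dict(self.minimum), "maximum": dict(self.maximum)}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(minimum=dict(d["minimum"]), maximum=dict(d["maximum"]))


def fit_minmax(table: pd.DataFrame) -> ScalerParams:
    """Fit per-column minima/maxima; raises naming any constant column."""
    mins, maxs = {}, {}
    for col in table.columns:
        lo, hi = float(table[col].min()), float(table[col].max())
        if not hi > lo:
            raise ValueError(f"column {col!r} is constant; min-max scaling undefined")
        mins[col], maxs[col] = lo, hi
    return ScalerParams(minimum=mins, maximum=maxs)


def apply_minmax(table: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    """(v - min) / (max - min) per fitted column."""
    out = table.copy()
    for col in params.minimum:
        lo, hi = params.minimum[col], params.maximum[col]
        out[col] = (table[col] - lo) / (hi - lo)
    return out


def invert_minmax(scaled: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    """Inverse of :func:`apply_minmax` (identity to floating precision)."""
    out = scaled.copy()
    for col in params.minimum:
        lo, hi = params.minimum[col], params.maximum[col]
        out[col] = scaled[col] * (hi - lo) + lo
    return out


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitResult:
    train_idx: np.ndarray
    test_idx: np.ndarray
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test indices overlap")


def train_test_split(table: pd.DataFrame, ratio: float, seed: int) -> SplitResult:
    """Uniform random split: first floor(ratio * n) of a seeded permutation
    become the training rows.  Indices are row positions, not labels.
    """
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    n_train = int(np.floor(ratio * n))
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves one side empty")
    perm = np.random.default_rng(seed).permutation(n)
    return SplitResult(
        train_idx=np.sort(perm[:n_train]),
        test_idx=np.sort(perm[n_train:]),
        ratio=ratio,
        seed=seed,
    )
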