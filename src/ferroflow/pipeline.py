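"""End-to-end study: simulate -> cleanse -> fit boosted surrogates -> report.

Stage seeds fan out from the single run seed by fixed offsets so each stage
is individually reproducible.
"""

from __future__ import annotations

import json
import logging
import pickle
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bat import SearchSpace, SwarmConfig, evaluate_fitness, tune
from .boosting import BoostEnsemble, fit_adaboost, predict_ensemble, staged_scores
from .config import RunConfig, dump_config
from .evaluation import (
    GridSpec,
    MetricReport,
    learning_curve,
    partial_dependence,
    prediction_surface,
    r2_score,
    rmse,
)
from .hemodynamics import (
    FlowField,
    FluidProperties,
    InletSpec,
    SolverConfig,
    build_grid,
    export_dataset,
    solve_flow,
)
from .magnetics import BodyForceField, MagneticMedium, MagnetSource, dipole_field, kelvin_body_force
from .preprocess import (
    IsolationForestConfig,
    ScalerParams,
    apply_minmax,
    fit_minmax,
    invert_minmax,
    remove_outliers,
    train_test_split,
)

log = logging.getLogger(__name__)

# stage-seed offsets (fan-out from the global run seed)
_SEED_OUTLIER = 11
_SEED_SPLIT = 23
_SEED_MODEL = {"tree": 31, "knn": 41, "mlp": 53}
_SEED_TUNER = 67
_SEED_CURVES = 79

MODEL_TAGS = {"tree": "ADA-DT", "knn": "ADA-KNN", "mlp": "ADA-MLP"}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# stage: simulate
# ---------------------------------------------------------------------------


def build_force(cfg: RunConfig, grid) -> BodyForceField:
    magnet = MagnetSource(
        position=tuple(cfg.magnet.position),
        moment_magnitude=cfg.magnet.moment,
        orientation_angle=cfg.magnet.angle,
    )
    medium = MagneticMedium(chi=cfg.magnet.chi)
    return kelvin_body_force(lambda p: dipole_field(p, magnet), grid.x, grid.y, medium)


def simulate(cfg: RunConfig) -> tuple[FlowField, pd.DataFrame]:
    """Run the CFD stage and build the (x, y, U) table."""
    g = cfg.flow.grid
    grid = build_grid(
        GridSpec(x_min=g.x_min, x_max=g.x_max, y_min=g.y_min, y_max=g.y_max, nx=g.nx, ny=g.ny)
    )
    props = FluidProperties(rho=cfg.flow.fluid.rho, mu=cfg.flow.fluid.mu)
    inlet = InletSpec(
        u_peak=cfg.flow.inlet.u_peak,
        pulse_amplitude=cfg.flow.inlet.pulse_amplitude,
        pulse_frequency=cfg.flow.inlet.pulse_frequency,
        phase_time=cfg.flow.inlet.phase,
    )
    s = cfg.flow.solver
    solver_cfg = SolverConfig(
        dt=s.dt,
        cfl=s.cfl,
        max_steps=s.max_steps,
        steady_tol=s.steady_tol,
        div_tol=s.div_tol,
        init=s.init,
    )
    force = build_force(cfg, grid)
    field = solve_flow(grid, props, inlet, force, solver_cfg)
    return field, export_dataset(field)


# ---------------------------------------------------------------------------
# stage: preprocess
# ---------------------------------------------------------------------------


@dataclass
class PreparedData:
    """Cleaned, split and scaled arrays plus everything needed to invert."""

    X_train: np.ndarray  # scaled inputs
    y_train: np.ndarray  # scaled target
    X_test: np.ndarray
    y_test: np.ndarray
    y_test_raw: np.ndarray  # m/s
    scaler: ScalerParams
    train_df: pd.DataFrame  # raw kept rows, training split
    test_df: pd.DataFrame
    removed: np.ndarray

    def invert_target(self, y_scaled: np.ndarray) -> np.ndarray:
        lo, hi = self.scaler.minimum["U"], self.scaler.maximum["U"]
        return y_scaled * (hi - lo) + lo


def prepare(df: pd.DataFrame, cfg: RunConfig) -> PreparedData:
    """Outlier removal, 80/20 split, min-max scaling fitted on train only."""
    p = cfg.preprocess
    if_cfg = IsolationForestConfig(
        n_trees=p.n_trees,
        subsample_size=min(p.subsample_size, len(df)),
        score_threshold=p.score_threshold,
        seed=cfg.seed + _SEED_OUTLIER,
    )
    kept, removed = remove_outliers(df, if_cfg)
    kept = kept.reset_index(drop=True)
    split = train_test_split(kept, p.ratio, cfg.seed + _SEED_SPLIT)
    train_df = kept.iloc[split.train_idx]
    test_df = kept.iloc[split.test_idx]
    scaler = fit_minmax(train_df)
    train_s = apply_minmax(train_df, scaler)
    test_s = apply_minmax(test_df, scaler)
    return PreparedData(
        X_train=train_s[["x", "y"]].to_numpy(),
        y_train=train_s["U"].to_numpy(),
        X_test=test_s[["x", "y"]].to_numpy(),
        y_test=test_s["U"].to_numpy(),
        y_test_raw=test_df["U"].to_numpy(),
        scaler=scaler,
        train_df=train_df,
        test_df=test_df,
        removed=removed,
    )


# ---------------------------------------------------------------------------
# stage: fit + evaluate one surrogate
# ---------------------------------------------------------------------------


class Surrogate:
    """Raw-scale interface of a fitted ensemble: (x, y) in metres -> U in
    m/s, optionally clipped at the physical floor U >= 0."""

    def __init__(self, ensemble: BoostEnsemble, scaler: ScalerParams, clip_negative=True):
        self.ensemble = ensemble
        self.scaler = scaler
        self.clip_negative = clip_negative

    def predict(self, XY) -> np.ndarray:
        XY = np.atleast_2d(np.asarray(XY, dtype=float))
        lo_x, hi_x = self.scaler.minimum["x"], self.scaler.maximum["x"]
        lo_y, hi_y = self.scaler.minimum["y"], self.scaler.maximum["y"]
        Xs = np.column_stack(
            [(XY[:, 0] - lo_x) / (hi_x - lo_x), (XY[:, 1] - lo_y) / (hi_y - lo_y)]
        )
        u_s = predict_ensemble(self.ensemble, Xs)
        lo_u, hi_u = self.scaler.minimum["U"], self.scaler.maximum["U"]
        u = u_s * (hi_u - lo_u) + lo_u
        return np.maximum(u, 0.0) if self.clip_negative else u


def base_hyperparams(cfg: RunConfig, family: str) -> dict:
    m = cfg.models
    if family == "tree":
        return {"max_depth": m.tree.max_depth, "min_samples_leaf": m.tree.min_samples_leaf}
    if family == "knn":
        return {"k": m.knn.k}
    if family == "mlp":
        return {
            "hidden_sizes": m.mlp.hidden_sizes,
            "activation": m.mlp.activation,
            "solver": m.mlp.solver,
            "learning_rate": m.mlp.learning_rate,
            "max_iter": m.mlp.max_iter,
        }
    raise ValueError(f"unknown family {family!r}")


def fit_surrogate(
    prep: PreparedData, family: str, cfg: RunConfig, n_estimators: int | None = None
) -> tuple[BoostEnsemble, MetricReport, Surrogate]:
    """Fit one boosted surrogate and score it on the raw-scale test split."""
    ensemble = fit_adaboost(
        prep.X_train,
        prep.y_train,
        base_family=family,
        base_hyperparams=base_hyperparams(cfg, family),
        n_estimators=n_estimators or cfg.ensemble.n_estimators(family),
        seed=cfg.seed + _SEED_MODEL[family],
        mode=cfg.ensemble.mode,
    )
    pred_raw = prep.invert_target(predict_ensemble(ensemble, prep.X_test))
    report = MetricReport(
        model=MODEL_TAGS[family],
        r2=r2_score(prep.y_test_raw, pred_raw),
        rmse=rmse(prep.y_test_raw, pred_raw),
        n_test=len(prep.y_test_raw),
    )
    return ensemble, report, Surrogate(ensemble, prep.scaler, cfg.evaluation.clip_negative)


class AdaModel:
    """fit/predict adapter over :func:`fit_adaboost` for curve diagnostics."""

    def __init__(self, family: str, hyperparams: dict, n_estimators: int, seed: int):
        self.family = family
        self.hyperparams = hyperparams
        self.n_estimators = n_estimators
        self.seed = seed
        self._ens: BoostEnsemble | None = None

    def fit(self, X, y):
        self._ens = fit_adaboost(
            X, y, self.family, self.hyperparams, n_estimators=self.n_estimators, seed=self.seed
        )
        return self

    def predict(self, X):
        return predict_ensemble(self._ens, X)


# ---------------------------------------------------------------------------
# stage: tune
# ---------------------------------------------------------------------------


def default_search_space(family: str) -> SearchSpace:
    if family == "tree":
        return SearchSpace.create([("max_depth", "integer", 1, 16)])
    if family == "knn":
        return SearchSpace.create([("k", "integer", 1, 16)])
    if family == "mlp":
        return SearchSpace.create([("hidden_sizes", "integer_tuple:2", 4, 96)])
    raise ValueError(f"unknown family {family!r}")


def tune_stage(prep: PreparedData, cfg: RunConfig):
    """BAT-tune the configured family on a subsample of the training split."""
    t = cfg.tuner
    rng = np.random.default_rng(cfg.seed + _SEED_TUNER)
    n = min(t.subsample, len(prep.y_train))
    idx = rng.choice(len(prep.y_train), size=n, replace=False)
    data = (prep.X_train[idx], prep.y_train[idx])
    spec = {
        "family": t.family,
        "base_hyperparams": base_hyperparams(cfg, t.family),
        "cv_folds": t.cv_folds,
    }
    space = default_search_space(t.family)
    swarm = SwarmConfig(
        n_bats=t.n_bats,
        n_iterations=t.n_iterations,
        f_min=t.f_min,
        f_max=t.f_max,
        seed=cfg.seed + _SEED_TUNER,
    )
    objective = lambda pos: evaluate_fitness(
        space.decode(pos), spec, data, seed=cfg.seed + _SEED_TUNER
    )
    return tune(space, swarm, objective)


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Execute the whole study into ``out_dir`` and return it.

    Writes the dataset CSV, per-model metric reports, the estimator-count
    curve, the learning curve, both partial-dependence curves, the
    prediction surface, serialized models and a provenance log.  Any stage
    failure aborts with the stage name and cause.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(handler)
    try:
        dump_config(cfg, out / "config.yaml")

        try:
            field, df = simulate(cfg)
            df.to_csv(out / "dataset.csv", index=False)
        except Exception as exc:
            raise StageError("simulate", exc)

        try:
            prep = prepare(df, cfg)
            (out / "scaler.json").write_text(json.dumps(prep.scaler.to_dict(), indent=2))
            (out / "split.json").write_text(
                json.dumps(
                    {
                        "n_removed": int(prep.removed.size),
                        "n_train": len(prep.train_df),
                        "n_test": len(prep.test_df),
                        "ratio": cfg.preprocess.ratio,
                    },
                    indent=2,
                )
            )
        except Exception as exc:
            raise StageError("preprocess", exc)

        if cfg.tuner.enabled:
            try:
                result = tune_stage(prep, cfg)
                pd.DataFrame(
                    {"iteration": np.arange(1, result.trace.size + 1), "best_fitness": result.trace}
                ).to_csv(out / "tuning_trace.csv", index=False)
                (out / "tuning_best.json").write_text(
                    json.dumps(
                        {"theta": result.best_theta, "fitness": result.best_fitness}, indent=2
                    )
                )
            except Exception as exc:
                raise StageError("tune", exc)

        surrogates: dict[str, Surrogate] = {}
        ensembles: dict[str, BoostEnsemble] = {}
        try:
            for family in ("tree", "knn", "mlp"):
                ens, report, surr = fit_surrogate(prep, family, cfg)
                tag = MODEL_TAGS[family]
                report.to_json(out / f"metrics_{tag}.json")
                surrogates[family] = surr
                ensembles[family] = ens
                log.info("%s: R2=%.5f RMSE=%.4e (n_test=%d)", tag, report.r2, report.rmse, report.n_test)
            with open(out / "models.pkl", "wb") as fh:
                pickle.dump(ensembles, fh)
        except Exception as exc:
            raise StageError("train", exc)

        try:
            ev = cfg.evaluation
            fam = ev.staged_family
            sc = staged_scores(ensembles[fam], prep.X_test, prep.y_test)
            pd.DataFrame(
                {"n_estimators": np.arange(1, sc.size + 1), "r2": sc}
            ).to_csv(out / f"staged_scores_{MODEL_TAGS[fam]}.csv", index=False)

            n_train = len(prep.y_train)
            sizes = [s for s in ev.lc_sizes if s <= n_train]
            if len(sizes) < 2:  # configured sizes don't fit a reduced dataset
                sizes = sorted({max(ev.lc_folds, n_train // 4), max(ev.lc_folds + 1, n_train // 2), n_train})
            lc_factory = lambda: AdaModel(
                "tree", base_hyperparams(cfg, "tree"), ev.lc_estimators, cfg.seed + _SEED_CURVES
            )
            s_arr, tr_sc, cv_sc = learning_curve(
                lc_factory,
                prep.X_train,
                prep.y_train,
                sizes,
                cv_folds=ev.lc_folds,
                seed=cfg.seed + _SEED_CURVES,
            )
            pd.DataFrame(
                {"train_size": s_arr, "train_r2": tr_sc, "cv_r2": cv_sc}
            ).to_csv(out / "learning_curve_ADA-DT.csv", index=False)

            background = prep.train_df[["x", "y"]].sample(
                n=min(ev.pd_background, len(prep.train_df)),
                random_state=cfg.seed + _SEED_CURVES,
            )
            for feat in ("x", "y"):
                curve = partial_dependence(
                    surrogates["tree"], background, feat, grid_size=ev.pd_grid_size
                )
                curve.to_csv(out / f"pd_{feat}.csv")

            g = cfg.flow.grid
            surf_spec = GridSpec(
                x_min=g.x_min, x_max=g.x_max, y_min=g.y_min, y_max=g.y_max,
                nx=ev.surface_nx, ny=ev.surface_ny,
            )
            dom = GridSpec(
                x_min=g.x_min, x_max=g.x_max, y_min=g.y_min, y_max=g.y_max, nx=g.nx, ny=g.ny
            )
            prediction_surface(surrogates["tree"], surf_spec, domain=dom).to_csv(
                out / "surface_ADA-DT.csv", index=False
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("evaluate", exc)

        provenance = {
            "ferroflow": __version__,
            "python": platform.python_version(),
            "seed": cfg.seed,
            "stage_seeds": {
                "outliers": cfg.seed + _SEED_OUTLIER,
                "split": cfg.seed + _SEED_SPLIT,
                **{f: cfg.seed + off for f, off in _SEED_MODEL.items()},
                "tuner": cfg.seed + _SEED_TUNER,
                "curves": cfg.seed + _SEED_CURVES,
            },
        }
        try:
            import numpy, pandas, scipy, sklearn

            provenance["versions"] = {
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pandas.__version__,
                "scikit-learn": sklearn.__version__,
            }
        except Exception:
            pass
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
        return out
    finally:
        logging.getLogger().removeHandler(handler)
        handler.close()
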