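"""Shared fixtures: the study-preset simulation and fitted surrogates are
expensive, so they are produced once per session and reused."""

from __future__ import annotations

import numpy as np
import pytest

from ferroflow.config import default_config
from ferroflow.hemodynamics import (
    FluidProperties,
    GridSpec,
    InletSpec,
    SolverConfig,
    build_grid,
    solve_flow,
)
from ferroflow.pipeline import fit_surrogate, prepare, simulate


@pytest.fixture(scope="session")
def study_cfg():
    return default_config(seed=1)


@pytest.fixture(scope="session")
def study_dataset(study_cfg):
    """Default-preset CFD run: the regenerated (x, y, U) table."""
    field, df = simulate(study_cfg)
    return field, df


@pytest.fixture(scope="session")
def study_prep(study_cfg, study_dataset):
    _, df = study_dataset
    return prepare(df, study_cfg)


@pytest.fixture(scope="session")
def ada_dt(study_cfg, study_prep):
    return fit_surrogate(study_prep, "tree", study_cfg)


@pytest.fixture(scope="session")
def ada_knn(study_cfg, study_prep):
    return fit_surrogate(study_prep, "knn", study_cfg)


@pytest.fixture(scope="session")
def ada_mlp(study_cfg, study_prep):
    # estimator count reduced from the tuned 180 to desk scale (<= 20)
    return fit_surrogate(study_prep, "mlp", study_cfg, n_estimators=12)


# --- a small, fast channel used by the solver tests ------------------------

SMALL_SPEC = GridSpec(x_min=0.0, x_max=2.0, y_min=0.0, y_max=1.0, nx=49, ny=25)
SMALL_PROPS = FluidProperties(rho=1.0, mu=0.1)
SMALL_INLET = InletSpec(u_peak=1.0, pulse_amplitude=0.0)


@pytest.fixture(scope="session")
def small_channel_flow():
    """Force-free flow in a unit-scale channel, started from rest."""
    grid = build_grid(SMALL_SPEC)
    field = solve_flow(
        grid,
        SMALL_PROPS,
        SMALL_INLET,
        None,
        SolverConfig(init="rest", steady_tol=1e-4),
    )
    return grid, field
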