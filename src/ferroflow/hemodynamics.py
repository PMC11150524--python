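"""2D incompressible channel-flow solver and velocity-dataset export.

The vessel segment is modelled as a plane channel (walls at ``y_min`` and
``y_max``), fed by a parabolic inlet profile modulated by a sinusoidal
heartbeat factor and driven, in addition to the pressure gradient, by the
magnetic Kelvin body force.  The steady momentum balance

    rho (U . grad) U = div( mu (grad U + grad U^T) ) - grad p + F,   div U = 0

is solved by pseudo-time marching a staggered-grid (MAC) explicit projection
scheme to steady state: upwind advection, centered diffusion, and an exact
sparse-direct pressure Poisson solve per step, which drives the discrete
divergence to round-off.  The converged field is interpolated to the grid
nodes and exported as the (x, y, U) table that the surrogate models learn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .magnetics import BodyForceField

log = logging.getLogger(__name__)


class SolverError(RuntimeError):
    """Raised when the flow solver cannot produce a valid solution."""


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Uniform structured node lattice over the channel rectangle.

    Defaults reproduce the study geometry: x in [-0.14, 0.08] m,
    y in [-0.02, -0.01] m, 425 x 41 nodes (17,425 > 17,000 samples).
    """

    x_min: float = -0.14
    x_max: float = 0.08
    y_min: float = -0.02
    y_max: float = -0.01
    nx: int = 425
    ny: int = 41

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("degenerate grid extents")
        if self.nx < 3 or self.ny < 3:
            raise ValueError("need at least 3 nodes per axis")


@dataclass(frozen=True)
class Grid:
    spec: GridSpec
    x: np.ndarray  # node coordinates, shape (nx,)
    y: np.ndarray  # node coordinates, shape (ny,)

    @property
    def dx(self) -> float:
        return (self.spec.x_max - self.spec.x_min) / (self.spec.nx - 1)

    @property
    def dy(self) -> float:
        return (self.spec.y_max - self.spec.y_min) / (self.spec.ny - 1)

    @property
    def xc(self) -> np.ndarray:
        """Cell-center x coordinates, shape (nx-1,)."""
        return 0.5 * (self.x[:-1] + self.x[1:])

    @property
    def yc(self) -> np.ndarray:
        """Cell-center y coordinates, shape (ny-1,)."""
        return 0.5 * (self.y[:-1] + self.y[1:])

    @property
    def n_nodes(self) -> int:
        return self.spec.nx * self.spec.ny


def build_grid(spec: GridSpec) -> Grid:
    """Build the uniform node lattice; corner nodes hit the extents exactly."""
    x = np.linspace(spec.x_min, spec.x_max, spec.nx)
    y = np.linspace(spec.y_min, spec.y_max, spec.ny)
    return Grid(spec=spec, x=x, y=y)


# ---------------------------------------------------------------------------
# fluid / inlet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian whole-blood defaults: rho = 1050 kg/m^3, mu = 3.5 mPa s."""

    rho: float = 1050.0
    mu: float = 3.5e-3

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")


@dataclass(frozen=True)
class InletSpec:
    """Parabolic inlet with sinusoidal heartbeat modulation.

    The inlet profile is
        u(y, t) = u_peak (1 - ((y - y_c)/h)^2) (1 + A sin(2 pi f t))
    with y_c the mid-gap and h the half-gap.  The study uses a single
    heartbeat-phase snapshot; ``phase_time`` selects it (default: systolic
    peak of a 72 bpm cycle, time factor 1 + A).
    """

    u_peak: float = 0.5 / 1.2
    pulse_amplitude: float = 0.2
    pulse_frequency: float = 1.2
    phase_time: float = 1.0 / (4.0 * 1.2)

    def __post_init__(self) -> None:
        if self.u_peak <= 0:
            raise ValueError("u_peak must be > 0")
        if not 0.0 <= self.pulse_amplitude < 1.0:
            raise ValueError("pulse_amplitude must be in [0, 1)")
        if self.time_factor() <= 0:
            raise ValueError("heartbeat time factor must be positive")

    def time_factor(self) -> float:
        return 1.0 + self.pulse_amplitude * np.sin(
            2.0 * np.pi * self.pulse_frequency * self.phase_time
        )


def inlet_profile(y, spec: InletSpec, walls: tuple[float, float]):
    """Inlet axial velocity at height(s) ``y`` between the walls.

    Raises if any ``y`` lies outside the gap.
    """
    y = np.asarray(y, dtype=float)
    y_lo, y_hi = walls
    if np.any(y < y_lo) or np.any(y > y_hi):
        raise ValueError("inlet_profile evaluated outside the channel gap")
    y_c = 0.5 * (y_lo + y_hi)
    h = 0.5 * (y_hi - y_lo)
    u = spec.u_peak * (1.0 - ((y - y_c) / h) ** 2) * spec.time_factor()
    return float(u) if u.ndim == 0 else u


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolverConfig:
    """Numerical controls for the pseudo-time projection march.

    ``steady_tol`` is a relative tolerance: the march stops when the maximum
    acceleration max|du/dt| falls below ``steady_tol * U^2 / L`` (U the peak
    inlet speed, L the channel length).  ``div_tol`` bounds the discrete
    divergence of the accepted solution (s^-1).
    """

    dt: float | None = None
    cfl: float = 0.4
    max_steps: int = 60_000
    steady_tol: float = 1e-4
    div_tol: float = 1e-6
    max_reynolds: float = 4000.0
    init: str = "poiseuille"  # or "rest"


@dataclass
class FlowField:
    """Converged staggered-grid solution plus node-interpolated velocities."""

    grid: Grid
    u_face: np.ndarray  # (nx, ny-1): u at vertical faces
    v_face: np.ndarray  # (nx-1, ny): v at horizontal faces
    p: np.ndarray  # (nx-1, ny-1): cell-center pressure
    steps: int
    residual: float

    def divergence(self) -> np.ndarray:
        """Cell-wise discrete divergence, shape (nx-1, ny-1), units s^-1."""
        dx, dy = self.grid.dx, self.grid.dy
        return (self.u_face[1:] - self.u_face[:-1]) / dx + (
            self.v_face[:, 1:] - self.v_face[:, :-1]
        ) / dy

    def node_velocities(self) -> tuple[np.ndarray, np.ndarray]:
        """Velocity components interpolated to the (nx, ny) node lattice.

        Wall rows are exactly zero (no slip).
        """
        nx, ny = self.grid.spec.nx, self.grid.spec.ny
        u = np.zeros((nx, ny))
        v = np.zeros((nx, ny))
        u[:, 1:-1] = 0.5 * (self.u_face[:, :-1] + self.u_face[:, 1:])
        v[1:-1, :] = 0.5 * (self.v_face[:-1, :] + self.v_face[1:, :])
        v[-1, :] = self.v_face[-1, :]
        v[0, :] = 0.0
        u[:, 0] = 0.0
        u[:, -1] = 0.0
        v[:, 0] = 0.0
        v[:, -1] = 0.0
        return u, v


def _poisson_lu(nxc: int, nyc: int, dx: float, dy: float):
    """Factorized 5-point Neumann Laplacian with cell 0 pinned to zero."""
    n = nxc * nyc
    idx = np.arange(n).reshape(nxc, nyc)
    rows, cols, vals = [], [], []
    ax, ay = 1.0 / dx**2, 1.0 / dy**2
    diag = np.zeros((nxc, nyc))
    for shift, axis, coef in ((1, 0, ax), (-1, 0, ax), (1, 1, ay), (-1, 1, ay)):
        src = np.roll(idx, -shift, axis=axis)
        if axis == 0:
            sl = (slice(0, -1), slice(None)) if shift == 1 else (slice(1, None), slice(None))
        else:
            sl = (slice(None), slice(0, -1)) if shift == 1 else (slice(None), slice(1, None))
        rows.append(idx[sl].ravel())
        cols.append(src[sl].ravel())
        vals.append(np.full(idx[sl].size, coef))
        diag[sl] -= coef
    rows = np.concatenate(rows + [np.arange(n)])
    cols = np.concatenate(cols + [np.arange(n)])
    vals = np.concatenate(vals + [diag.ravel()])
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n)).tolil()
    A.rows[0] = [0]
    A.data[0] = [1.0]
    return splu(A.tocsc())


def _force_on_faces(force: BodyForceField | None, grid: Grid):
    """Average the node force field onto the u and v face locations."""
    nx, ny = grid.spec.nx, grid.spec.ny
    if force is None:
        return np.zeros((nx, ny - 1)), np.zeros((nx - 1, ny))
    if force.fx.shape != (nx, ny):
        raise ValueError("body force is not defined on the solver grid")
    fx_u = 0.5 * (force.fx[:, :-1] + force.fx[:, 1:])
    fy_v = 0.5 * (force.fy[:-1, :] + force.fy[1:, :])
    return fx_u, fy_v


def solve_flow(
    grid: Grid,
    props: FluidProperties,
    inlet: InletSpec,
    force: BodyForceField | None = None,
    solver_cfg: SolverConfig | None = None,
) -> FlowField:
    """March the projection scheme to the steady heartbeat-phase solution.

    Raises :class:`SolverError` on non-convergence (reporting the final
    residual), on a Reynolds number beyond the scheme's range, or if the
    accepted solution violates the divergence contract.
    """
    cfg = solver_cfg or SolverConfig()
    spec = grid.spec
    nx, ny = spec.nx, spec.ny
    nxc, nyc = nx - 1, ny - 1
    dx, dy = grid.dx, grid.dy
    rho, nu = props.rho, props.mu / props.rho

    gap = spec.y_max - spec.y_min
    u_max = inlet.u_peak * inlet.time_factor()
    reynolds = u_max * gap / nu
    if reynolds > cfg.max_reynolds:
        raise SolverError(
            f"Reynolds number {reynolds:.0f} exceeds the scheme limit {cfg.max_reynolds:.0f}"
        )

    u_in = inlet_profile(grid.yc, inlet, (spec.y_min, spec.y_max))

    dt = cfg.dt
    if dt is None:
        dt = cfg.cfl * min(
            dx / u_max, dy / max(u_max, 1e-30), dy**2 / (4.0 * nu), dx**2 / (4.0 * nu)
        )

    u = np.zeros((nx, nyc))
    v = np.zeros((nxc, ny))
    if cfg.init == "poiseuille":
        u[:] = u_in[None, :]
    u[0] = u_in

    fx_u, fy_v = _force_on_faces(force, grid)
    lu = _poisson_lu(nxc, nyc, dx, dy)

    tol_abs = cfg.steady_tol * u_max**2 / (spec.x_max - spec.x_min)
    residual = np.inf
    q_in = u_in.sum() * dy

    for step in range(1, cfg.max_steps + 1):
        un, vn = u, v

        # --- u predictor (interior faces i = 1 .. nx-2) -------------------
        upad = np.concatenate([-u[:, :1], u, -u[:, -1:]], axis=1)  # wall ghosts
        ui = u[1:-1]
        dudx_m = (u[1:-1] - u[:-2]) / dx
        dudx_p = (u[2:] - u[1:-1]) / dx
        adv_x = np.where(ui > 0, ui * dudx_m, ui * dudx_p)
        vau = 0.25 * (v[:-1, :-1] + v[:-1, 1:] + v[1:, :-1] + v[1:, 1:])
        dudy_m = (u - upad[:, :-2]) / dy
        dudy_p = (upad[:, 2:] - u) / dy
        adv_y = np.where(vau > 0, vau * dudy_m[1:-1], vau * dudy_p[1:-1])
        lap_u = (u[2:] - 2.0 * ui + u[:-2]) / dx**2 + (
            upad[1:-1, 2:] - 2.0 * ui + upad[1:-1, :-2]
        ) / dy**2
        ustar = u.copy()
        ustar[1:-1] = ui + dt * (-adv_x - adv_y + nu * lap_u + fx_u[1:-1] / rho)

        # --- v predictor (interior rows j = 1 .. ny-2) --------------------
        vpad = np.concatenate([-v[:1], v, v[-1:]], axis=0)  # inlet Dirichlet, outlet Neumann
        vi = v[:, 1:-1]
        uav = 0.25 * (u[:-1, :-1] + u[:-1, 1:] + u[1:, :-1] + u[1:, 1:])
        dvdx_m = (v - vpad[:-2]) / dx
        dvdx_p = (vpad[2:] - v) / dx
        adv_xv = np.where(uav > 0, uav * dvdx_m[:, 1:-1], uav * dvdx_p[:, 1:-1])
        dvdy_m = (vi - v[:, :-2]) / dy
        dvdy_p = (v[:, 2:] - vi) / dy
        adv_yv = np.where(vi > 0, vi * dvdy_m, vi * dvdy_p)
        lap_v = (vpad[2:, 1:-1] - 2.0 * vi + vpad[:-2, 1:-1]) / dx**2 + (
            v[:, 2:] - 2.0 * vi + v[:, :-2]
        ) / dy**2
        vstar = v.copy()
        vstar[:, 1:-1] = vi + dt * (-adv_xv - adv_yv + nu * lap_v + fy_v[:, 1:-1] / rho)
        vstar[:, 0] = 0.0
        vstar[:, -1] = 0.0

        # --- boundary conditions + global mass balance --------------------
        ustar[0] = u_in
        ustar[-1] = ustar[-2]
        q_out = ustar[-1].sum() * dy
        ustar[-1] += (q_in - q_out) / (nyc * dy)

        # --- projection ---------------------------------------------------
        div = (ustar[1:] - ustar[:-1]) / dx + (vstar[:, 1:] - vstar[:, :-1]) / dy
        rhs = (rho / dt) * div.ravel()
        rhs[0] = 0.0
        p = lu.solve(rhs).reshape(nxc, nyc)
        u = ustar.copy()
        v = vstar.copy()
        u[1:-1] -= (dt / rho) * (p[1:] - p[:-1]) / dx
        v[:, 1:-1] -= (dt / rho) * (p[:, 1:] - p[:, :-1]) / dy

        residual = max(np.abs(u - un).max(), np.abs(v - vn).max()) / dt
        if residual <= tol_abs:
            break
    else:
        raise SolverError(
            f"flow solver did not reach steady state in {cfg.max_steps} steps "
            f"(final residual {residual:.3e} m/s^2, tolerance {tol_abs:.3e})"
        )

    field = FlowField(grid=grid, u_face=u, v_face=v, p=p, steps=step, residual=residual)
    max_div = np.abs(field.divergence()).max()
    if max_div > cfg.div_tol:
        raise SolverError(f"discrete divergence {max_div:.3e} exceeds {cfg.div_tol:.1e}")
    log.info("flow converged in %d steps (residual %.3e, max div %.3e)", step, residual, max_div)
    return field


# ---------------------------------------------------------------------------
# dataset export
# ---------------------------------------------------------------------------


def export_dataset(field: FlowField, path: str | Path | None = None) -> pd.DataFrame:
    """Build (and optionally write) the (x, y, U) node table.

    ``U`` is the velocity magnitude sqrt(u^2 + v^2); one row per grid node,
    wall rows exactly zero.  Written as a plain CSV with header ``x,y,U`` at
    full float precision, so a read-back reproduces the table bit-exactly.
    """
    u, v = field.node_velocities()
    X, Y = np.meshgrid(field.grid.x, field.grid.y, indexing="ij")
    df = pd.DataFrame(
        {"x": X.ravel(), "y": Y.ravel(), "U": np.hypot(u, v).ravel()}
    )
    if path is not None:
        df.to_csv(path, index=False, float_format="%.17g")  # bit-exact round trip
    return df
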