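"""External magnet model and the magnetic body force on the carrier fluid.

Blood carrying magnetizable drug nanocarriers behaves, at dilute loading, as
a linearly magnetizable medium: an external field ``H`` magnetizes the fluid
(``M = chi * H``) and the resulting Kelvin body-force density

    F = mu0 * chi * (H . grad) H        [N / m^3]

enters the momentum balance of the flow solver.  The external permanent
magnet is represented by a point dipole placed outside the vessel wall; its
field decays with the inverse cube of distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: vacuum permeability, T m / A
MU0 = 4.0e-7 * np.pi


class SingularFieldError(ValueError):
    """Raised when the dipole field is evaluated at the dipole position."""


@dataclass(frozen=True)
class MagnetSource:
    """A point-dipole permanent magnet.

    Parameters
    ----------
    position:
        (x, y) location of the dipole in metres.  Must lie outside the flow
        domain (checked by the flow configuration, not here).
    moment_magnitude:
        Dipole moment magnitude, A m^2.  Zero gives an identically zero field.
    orientation_angle:
        Angle of the moment vector measured from the +x axis, radians.
        ``pi/2`` points the magnet at a channel above it.
    """

    position: tuple[float, float]
    moment_magnitude: float
    orientation_angle: float = np.pi / 2.0

    def __post_init__(self) -> None:
        if self.moment_magnitude < 0:
            raise ValueError("moment_magnitude must be >= 0")

    @property
    def moment(self) -> np.ndarray:
        """Moment vector m = |m| (cos a, sin a)."""
        a = self.orientation_angle
        return self.moment_magnitude * np.array([np.cos(a), np.sin(a)])


@dataclass(frozen=True)
class MagneticMedium:
    """Linear magnetic constitutive parameters of the carrier fluid."""

    mu0: float = MU0
    chi: float = 0.05

    def __post_init__(self) -> None:
        if self.mu0 <= 0:
            raise ValueError("mu0 must be > 0")
        if self.chi < 0:
            raise ValueError("chi must be >= 0")


def dipole_field(point, source: MagnetSource) -> np.ndarray:
    """Magnetic field H (A/m) of a point dipole at one or more points.

    Uses the point-dipole expression evaluated in the plane of the flow,

        H(r) = (3 (m . r_hat) r_hat - m) / (4 pi |r|^3),

    so the field magnitude decays as 1/|r|^3.

    Parameters
    ----------
    point:
        Shape (2,) or (N, 2) array of evaluation points, metres.
    source:
        The dipole.

    Returns
    -------
    H with the same leading shape as ``point``.
    """
    pts = np.asarray(point, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    r = pts - np.asarray(source.position, dtype=float)
    rn = np.linalg.norm(r, axis=1)
    if np.any(rn == 0.0):
        raise SingularFieldError("dipole field evaluated at the source position")
    m = source.moment
    rhat = r / rn[:, None]
    mdotr = rhat @ m
    H = (3.0 * mdotr[:, None] * rhat - m) / (4.0 * np.pi * rn[:, None] ** 3)
    return H[0] if single else H


@dataclass
class BodyForceField:
    """Kelvin force density evaluated on the nodes of a structured grid.

    ``fx`` and ``fy`` have shape ``(nx, ny)`` with the grid's node ordering
    (x index first).
    """

    x: np.ndarray
    y: np.ndarray
    fx: np.ndarray
    fy: np.ndarray

    def __post_init__(self) -> None:
        shape = (self.x.size, self.y.size)
        if self.fx.shape != shape or self.fy.shape != shape:
            raise ValueError("force arrays must have shape (nx, ny)")
        if not (np.all(np.isfinite(self.fx)) and np.all(np.isfinite(self.fy))):
            raise ValueError("force components must be finite")

    @classmethod
    def zero(cls, x: np.ndarray, y: np.ndarray) -> "BodyForceField":
        shape = (x.size, y.size)
        return cls(x=x, y=y, fx=np.zeros(shape), fy=np.zeros(shape))


def kelvin_body_force(field_sampler, x, y, medium: MagneticMedium) -> BodyForceField:
    """Evaluate F = mu0 chi (H . grad) H on a structured node lattice.

    Parameters
    ----------
    field_sampler:
        Callable mapping an (N, 2) array of points to an (N, 2) array of H
        vectors (A/m), e.g. ``lambda p: dipole_field(p, magnet)``.
    x, y:
        1-D node coordinate arrays (at least 3 nodes per axis; the gradient
        is centered in the interior and one-sided at the boundary).
    medium:
        Magnetic constitutive parameters.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("kelvin_body_force needs at least 3 nodes per axis")
    X, Y = np.meshgrid(x, y, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    H = np.asarray(field_sampler(pts), dtype=float)
    Hx = H[:, 0].reshape(X.shape)
    Hy = H[:, 1].reshape(X.shape)

    dHx_dx = np.gradient(Hx, x, axis=0)
    dHx_dy = np.gradient(Hx, y, axis=1)
    dHy_dx = np.gradient(Hy, x, axis=0)
    dHy_dy = np.gradient(Hy, y, axis=1)

    c = medium.mu0 * medium.chi
    fx = c * (Hx * dHx_dx + Hy * dHx_dy)
    fy = c * (Hx * dHy_dx + Hy * dHy_dy)
    return BodyForceField(x=x, y=y, fx=fx, fy=fy)
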