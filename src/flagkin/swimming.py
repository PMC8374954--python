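"""Projected free-swimming trajectories from the tethered waveform.

If the tether were removed, inertia-free (low Reynolds number) mechanics
requires the net hydrodynamic force on the cell to vanish at every instant.
Assuming the beat shape is unchanged after untethering, each material point
then moves at u + U, where u is the observed undulatory velocity and U(τ) is
an unknown rigid translation.  The force-free condition

    ∫ ζ̂(s, τ) · (u + U) ds = 0,     ζ̂ = ζ_t t̂ t̂ + ζ_n n̂ n̂,

gives U(τ) = −A(τ)⁻¹ b(τ) with A = ∫ ζ̂ ds (the 2×2 friction tensor, always
symmetric positive definite for a filament of nonzero length) and
b = ∫ ζ̂ · u ds.  The projected trajectory R(τ) is the time integral of U,
and the straight-line velocity VSL is the net displacement per beat cycle
divided by the period.

Torque balance is deliberately not imposed: the projection yields a
translation velocity only, and rotation of the hypothetical swimmer is
neglected.  A reciprocal (standing-wave) beat therefore yields no net
displacement — the numerical scallop theorem — which is used as a
correctness check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline

from .centerline import CenterlineSeries, VelocityField, velocities
from .errors import GeometryError, ParameterError
from .rft import UM, RFTParameters, friction_coefficients

__all__ = [
    "ProjectedTrajectory",
    "friction_tensor_integral",
    "translation_velocity",
    "trajectory_and_vsl",
    "project_free_swimming",
]


@dataclass
class ProjectedTrajectory:
    """Projected free-swimmer kinematics (μm, μm/s)."""

    U: np.ndarray  # (N, 2) translation velocity, μm/s
    R: np.ndarray  # (N, 2) trajectory, μm, R[0] = (0, 0)
    times: np.ndarray  # (N,), s
    vsl: float  # μm/s, mean over complete cycles
    vsl_first_cycle: float  # μm/s, first complete cycle only
    n_cycles: int
    period: float  # s
    max_residual: float  # worst relative force-free residual over frames


def friction_tensor_integral(
    v: VelocityField, params: RFTParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame A(τ) = ∫ ζ̂ ds (N, 2, 2) [N·s/m] and b(τ) = ∫ ζ̂·u ds (N, 2) [N].

    A is symmetric positive definite whenever ζ_t, ζ_n > 0 and the filament
    has nonzero length.
    """
    zeta_t, zeta_n = friction_coefficients(v.arc_grid, params)
    # ζ̂ = ζ_t t̂t̂ + ζ_n n̂n̂ at every (frame, point): (N, M, 2, 2)
    tt = np.einsum("nmi,nmj->nmij", v.t_hat, v.t_hat)
    nn = np.einsum("nmi,nmj->nmij", v.n_hat, v.n_hat)
    zeta = zeta_t[None, :, None, None] * tt + zeta_n[None, :, None, None] * nn
    s_m = v.arc_grid * UM
    A = np.trapezoid(zeta, s_m, axis=1)  # (N, 2, 2)
    u = np.stack([v.u_x, v.u_y], axis=-1) * UM  # (N, M, 2), m/s
    zu = np.einsum("nmij,nmj->nmi", zeta, u)
    b = np.trapezoid(zu, s_m, axis=1)  # (N, 2)
    min_eig = np.linalg.eigvalsh(A)[:, 0].min()
    if min_eig <= 0:
        raise GeometryError("friction tensor integral not positive definite")
    return A, b


def translation_velocity(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Force-free translation velocity U = −A⁻¹ b (μm/s) and the per-frame
    relative residual ‖A·U + b‖ / ‖b‖ (0 where b vanishes)."""
    U_si = -np.linalg.solve(A, b[..., None])[..., 0]  # m/s
    res = np.einsum("nij,nj->ni", A, U_si) + b
    bn = np.linalg.norm(b, axis=1)
    rn = np.linalg.norm(res, axis=1)
    residual = np.where(bn > 0, rn / np.where(bn > 0, bn, 1.0), 0.0)
    return U_si / UM, residual


def trajectory_and_vsl(
    U: np.ndarray,
    times: np.ndarray,
    period: float,
) -> ProjectedTrajectory:
    """Integrate the translation velocity and compute the straight-line
    velocity.

    R(τ) is the cumulative trapezoidal integral of U from the first frame.
    VSL is the magnitude of the displacement over one beat period divided by
    the period, averaged over all complete periods in the record (the
    single-cycle value is also kept).
    """
    U = np.asarray(U, dtype=float)
    times = np.asarray(times, dtype=float)
    if period <= 0:
        raise ParameterError("period must be positive")
    duration = times[-1] - times[0]
    n_cycles = int(np.floor(duration / period + 1e-9))
    if n_cycles < 1:
        raise ParameterError(
            f"record ({duration:.3f} s) shorter than one beat period ({period:.3f} s)"
        )
    R = cumulative_trapezoid(U, times, axis=0, initial=0.0)
    edges = times[0] + period * np.arange(n_cycles + 1)
    # cycle boundaries rarely fall on frame times; R oscillates strongly
    # within a cycle, so evaluate the edges with a cubic spline (linear
    # interpolation would dominate the per-cycle displacement error)
    R_edges = CubicSpline(times, R, axis=0)(edges)
    disp = np.hypot(np.diff(R_edges[:, 0]), np.diff(R_edges[:, 1]))
    vsl_all = float(disp.mean() / period)
    return ProjectedTrajectory(
        U=U,
        R=R,
        times=times,
        vsl=vsl_all,
        vsl_first_cycle=float(disp[0] / period),
        n_cycles=n_cycles,
        period=float(period),
        max_residual=np.nan,
    )


def project_free_swimming(
    c: CenterlineSeries,
    params: RFTParameters,
    period: float,
    v: VelocityField | None = None,
) -> ProjectedTrajectory:
    """Full projection: velocities -> force-free U(τ) -> trajectory and VSL."""
    if v is None:
        v = velocities(c)
    A, b = friction_tensor_integral(v, params)
    U, residual = translation_velocity(A, b)
    traj = trajectory_and_vsl(U, v.times, period)
    traj.max_residual = float(residual.max())
    return traj
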