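"""Resistive-force-theory (RFT) hydrodynamics of the beating flagellum.

At low Reynolds number the hydrodynamic force per unit length on a slender
filament is local and anisotropic:

    f(s, τ) = ζ_t u_t t̂ + ζ_n u_n n̂,

with wall-corrected friction coefficients

    ζ_t = 2πμ / ln(2h/a),    ζ_n = 4πμ / ln(2h/a),

where μ is the medium viscosity, h the distance from the nearby glass wall
(approximated by the head-end radius, since the tethered tail beats parallel
and close to the surface), and a(s) the flagellar radius with a linear taper
from ``a_h`` at the base to ``a_t`` at the tip.

The instantaneous dissipation density is p = f · u = ζ_t u_t² + ζ_n u_n²
(≥ 0 by construction); its time average p̄(s) and the whole-cell rate
E = ∫ p̄ ds (femtowatts for mouse sperm) are evaluated with the trapezoidal
rule.  User-facing quantities stay in μm/s/cP units; conversion to SI happens
inside this module only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .centerline import VelocityField
from .errors import ParameterError

__all__ = [
    "RFTParameters",
    "PowerFields",
    "taper_radius",
    "friction_coefficients",
    "force_density",
    "power_fields",
]

UM = 1e-6  # μm -> m


@dataclass
class RFTParameters:
    """Friction-model constants.

    viscosity : Pa·s (default 1e-3 = 1 cP, low-viscosity medium)
    a_h, a_t  : μm, flagellar radii at the head end and tip (0.57, 0.18)
    L         : μm, flagellum length (110)
    h         : μm, distance from the wall; defaults to a_h
    """

    viscosity: float = 1e-3
    a_h: float = 0.57
    a_t: float = 0.18
    L: float = 110.0
    h: float | None = None

    def __post_init__(self) -> None:
        if self.h is None:
            self.h = self.a_h
        if min(self.viscosity, self.a_h, self.a_t, self.L, self.h) <= 0:
            raise ParameterError("all RFT parameters must be positive")
        if self.a_t > self.a_h:
            raise ParameterError("tip radius a_t must not exceed head radius a_h")
        if 2.0 * self.h / self.a_h <= 1.0:
            raise ParameterError("wall distance too small: 2h/a must exceed 1 everywhere")


@dataclass
class PowerFields:
    """Force and power-dissipation fields in SI units."""

    f_x: np.ndarray  # (N, M), N/m
    f_y: np.ndarray  # (N, M), N/m
    p: np.ndarray  # (N, M), W/m, instantaneous dissipation density
    p_bar: np.ndarray  # (M,), W/m, time-averaged density
    E: float  # W, whole-cell dissipation rate
    arc_grid: np.ndarray  # (M,), μm
    times: np.ndarray  # (N,), s

    @property
    def E_fW(self) -> float:
        """Whole-cell dissipation rate in femtowatts."""
        return self.E * 1e15


def taper_radius(s, params: RFTParameters) -> np.ndarray:
    """Flagellar radius a(s) = (a_h - a_t)(L - s)/L + a_t, μm."""
    s = np.asarray(s, dtype=float)
    if np.any(s < -1e-9) or np.any(s > params.L * (1 + 1e-9)):
        raise ParameterError(f"arc coordinate outside [0, {params.L}] μm")
    return (params.a_h - params.a_t) * (params.L - s) / params.L + params.a_t


def friction_coefficients(s, params: RFTParameters) -> tuple[np.ndarray, np.ndarray]:
    """Wall-corrected local friction coefficients (ζ_t, ζ_n) in Pa·s.

    ζ_n = 2 ζ_t exactly, the slender-filament near-wall anisotropy.
    """
    a = taper_radius(s, params)
    log_arg = 2.0 * params.h / a
    if np.any(log_arg <= 1.0):
        raise ParameterError("wall closer than filament radius: ln(2h/a) <= 0")
    zeta_t = 2.0 * np.pi * params.viscosity / np.log(log_arg)
    return zeta_t, 2.0 * zeta_t


def force_density(v: VelocityField, params: RFTParameters) -> tuple[np.ndarray, np.ndarray]:
    """Hydrodynamic force per unit length (f_x, f_y) in N/m.

    Velocities are taken in μm/s and converted to SI internally.
    """
    if v.arc_grid is None:
        raise ParameterError("velocity field lacks an arc grid")
    if abs(v.arc_grid[-1] - params.L) > 0.01 * params.L:
        raise ParameterError(
            f"arc grid ends at {v.arc_grid[-1]:.2f} μm but RFT length is {params.L} μm"
        )
    zeta_t, zeta_n = friction_coefficients(v.arc_grid, params)
    ft = zeta_t[None, :] * v.u_t * UM  # N/m
    fn = zeta_n[None, :] * v.u_n * UM
    f_x = ft * v.t_hat[..., 0] + fn * v.n_hat[..., 0]
    f_y = ft * v.t_hat[..., 1] + fn * v.n_hat[..., 1]
    return f_x, f_y


def power_fields(v: VelocityField, params: RFTParameters, *, trim_boundary_frames: int = 0) -> PowerFields:
    """Dissipation fields p(s, τ), p̄(s) and the whole-cell rate E.

    p = ζ_t u_t² + ζ_n u_n² is non-negative for any motion.  The time average
    runs over the full record (T = total duration); ``trim_boundary_frames``
    drops that many frames at each end first, excluding the one-sided
    velocity stencils if desired.  Integrals use the trapezoidal rule.
    """
    if v.times is None or v.times.shape[0] < 3:
        raise ParameterError("need >= 3 frames for time averaging")
    zeta_t, zeta_n = friction_coefficients(v.arc_grid, params)
    ut = v.u_t * UM  # m/s
    un = v.u_n * UM
    p = zeta_t[None, :] * ut**2 + zeta_n[None, :] * un**2  # W/m
    f_x, f_y = force_density(v, params)

    k = trim_boundary_frames
    if k < 0 or 2 * k >= v.times.shape[0] - 1:
        raise ParameterError("trim_boundary_frames leaves fewer than 2 frames")
    sl = slice(k, v.times.shape[0] - k if k else None)
    t_used = v.times[sl]
    T = t_used[-1] - t_used[0]
    p_bar = np.trapezoid(p[sl], t_used, axis=0) / T
    E = float(np.trapezoid(p_bar, v.arc_grid * UM))
    return PowerFields(
        f_x=f_x, f_y=f_y, p=p, p_bar=p_bar, E=E,
        arc_grid=v.arc_grid.copy(), times=v.times.copy(),
    )
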