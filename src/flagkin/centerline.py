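"""Centerline data model and differential geometry.

A head-tethered sperm cell is recorded as a time series of planar flagellar
centerlines.  The in-memory representation is :class:`CenterlineSeries`:
positions on a common uniform arc-length grid across frames, in micrometres
and seconds.  From it the pipeline derives the tangent-angle field
``psi(s, tau)`` (the substrate of the shape-mode decomposition), material
point velocities with their tangential/normal split, and — inversely — a
centerline reconstructed from tangent angles by quadrature.

Conventions
-----------
* ``s = 0`` at the flagellar base (head/neck junction), ``s = L`` at the tip.
* Lab frame right-handed; the unit normal is the tangent rotated by +90 deg.
* Micrometres and seconds throughout this module; SI conversion happens only
  at the hydrodynamics boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import splev, splrep

from .errors import DataError, GeometryError, InsufficientDataError

__all__ = [
    "CenterlineSeries",
    "TangentAngleField",
    "VelocityField",
    "tangent_angles",
    "reconstruct_centerline",
    "velocities",
    "resample_polyline",
]

_TWO_PI = 2.0 * np.pi


@dataclass
class CenterlineSeries:
    """Planar centerline positions on a common arc-length grid.

    Parameters
    ----------
    times : (N,) array
        Frame times in seconds, strictly increasing, nominally uniform at
        ``1/fps``.
    arc_grid : (M,) array
        Arc-length coordinates in micrometres, uniform from 0 (head/neck
        junction) to ``body_length`` (tip).
    x, y : (N, M) arrays
        Positions in micrometres.
    fps : float
        Nominal acquisition rate, frames per second.
    body_length : float
        Flagellum length L in micrometres (mouse sperm: 110).
    """

    times: np.ndarray
    arc_grid: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fps: float = 400.0
    body_length: float = 110.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.arc_grid = np.asarray(self.arc_grid, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)

    # -- basic shape accessors -------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def n_points(self) -> int:
        return self.arc_grid.shape[0]

    def head_displacement(self) -> float:
        """Maximum excursion of the head point from its time-mean (μm)."""
        hx, hy = self.x[:, 0], self.y[:, 0]
        return float(np.hypot(hx - hx.mean(), hy - hy.mean()).max())

    def validate(
        self,
        *,
        chord_tol: float = 0.02,
        tether_tol: float = 2.0,
        tethered: bool = True,
    ) -> "CenterlineSeries":
        """Check the structural invariants; return self for chaining.

        Raises
        ------
        DataError
            Non-monotone times/arc grid, NaNs, chord lengths deviating from
            the arc spacing by more than ``chord_tol``, or (for tethered
            data) head displacement above ``tether_tol`` μm.
        InsufficientDataError
            Fewer than 3 frames or 5 arc points.
        """
        if self.n_frames < 3 or self.n_points < 5:
            raise InsufficientDataError(
                f"need >=3 frames and >=5 points, got {self.n_frames}x{self.n_points}"
            )
        if self.x.shape != (self.n_frames, self.n_points) or self.y.shape != self.x.shape:
            raise DataError("x/y shapes do not match times x arc_grid")
        if not np.all(np.diff(self.times) > 0):
            raise DataError("times must be strictly increasing")
        ds = np.diff(self.arc_grid)
        if not np.all(ds > 0):
            raise DataError("arc_grid must be strictly increasing")
        if abs(self.arc_grid[0]) > 1e-9:
            raise DataError("arc_grid must start at 0 (head/neck junction)")
        if abs(self.arc_grid[-1] - self.body_length) > 0.01 * self.body_length:
            raise DataError(
                f"arc_grid ends at {self.arc_grid[-1]:.3f}, expected body_length={self.body_length}"
            )
        for a in (self.times, self.arc_grid, self.x, self.y):
            if not np.all(np.isfinite(a)):
                raise DataError("non-finite values in centerline data")
        chords = np.hypot(np.diff(self.x, axis=1), np.diff(self.y, axis=1))
        rel = np.abs(chords - ds[None, :]) / ds[None, :]
        if rel.max() > chord_tol:
            raise DataError(
                f"chord lengths deviate from arc spacing by {rel.max():.1%} "
                f"(tolerance {chord_tol:.0%}); resample the input"
            )
        if tethered and self.head_displacement() > tether_tol:
            raise DataError(
                f"head point moves {self.head_displacement():.2f} μm, above the "
                f"tether tolerance {tether_tol} μm"
            )
        return self


@dataclass
class TangentAngleField:
    """Tangent angle ψ(s, τ): the angle of the local tangent with the
    horizontal lab axis, in radians, unwrapped along arc length per frame and
    branch-continuous in time at the head segment."""

    psi: np.ndarray  # (N, M), radians
    arc_grid: np.ndarray  # (M,), μm
    times: np.ndarray  # (N,), s
    fps: float = 400.0
    body_length: float = 110.0

    @property
    def n_frames(self) -> int:
        return self.psi.shape[0]

    @property
    def n_points(self) -> int:
        return self.psi.shape[1]


@dataclass
class VelocityField:
    """Material-point velocities of the centerline and their decomposition
    into tangential and normal components (μm/s).

    ``u_t * t_hat + u_n * n_hat`` reconstructs ``(u_x, u_y)`` exactly because
    (t̂, n̂) is an orthonormal basis at every point.
    """

    u_x: np.ndarray  # (N, M), μm/s
    u_y: np.ndarray
    u_t: np.ndarray
    u_n: np.ndarray
    t_hat: np.ndarray  # (N, M, 2), unit tangent
    n_hat: np.ndarray  # (N, M, 2), unit normal (tangent rotated +90°)
    arc_grid: np.ndarray = field(default=None)  # type: ignore[assignment]
    times: np.ndarray = field(default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# geometry operations
# ---------------------------------------------------------------------------


def tangent_angles(c: CenterlineSeries) -> TangentAngleField:
    """Tangent-angle field of a centerline series.

    ψ is the angle of (∂x/∂s, ∂y/∂s), computed with second-order central
    differences (one-sided at the ends), unwrapped along arc length within
    each frame, and made branch-continuous in time by anchoring the head
    segment: whole 2π jumps of the head angle between consecutive frames are
    removed so the field is coherent for the shape-mode decomposition.
    """
    dxds = np.gradient(c.x, c.arc_grid, axis=1, edge_order=2)
    dyds = np.gradient(c.y, c.arc_grid, axis=1, edge_order=2)
    speed = np.hypot(dxds, dyds)
    if np.any(speed < 1e-9):
        raise GeometryError("zero-length tangent (coincident centerline points)")
    psi = np.unwrap(np.arctan2(dyds, dxds), axis=1)
    # Inter-frame branch continuity: each frame's unwrap starts from the
    # head point's principal branch, so whole frames can land 2π apart.
    # Anchor on the frame-mean angle (tracking noise on any single point —
    # the head especially, with its one-sided stencil — can flip that
    # point's angle by ~π, while the frame mean is √M times quieter).
    head = psi.mean(axis=1)
    jumps = np.round(np.diff(head) / _TWO_PI)
    offsets = np.concatenate(([0.0], np.cumsum(jumps))) * _TWO_PI
    psi = psi - offsets[:, None]
    return TangentAngleField(
        psi=psi,
        arc_grid=c.arc_grid.copy(),
        times=c.times.copy(),
        fps=c.fps,
        body_length=c.body_length,
    )


def reconstruct_centerline(
    t: TangentAngleField, head_xy: tuple[float, float] = (0.0, 0.0)
) -> CenterlineSeries:
    """Centerline positions from tangent angles by cumulative trapezoidal
    quadrature:  x(s) = x_h + ∫₀ˢ cos ψ ds',  y(s) = y_h + ∫₀ˢ sin ψ ds'."""
    x = head_xy[0] + cumulative_trapezoid(np.cos(t.psi), t.arc_grid, axis=1, initial=0.0)
    y = head_xy[1] + cumulative_trapezoid(np.sin(t.psi), t.arc_grid, axis=1, initial=0.0)
    return CenterlineSeries(
        times=t.times.copy(),
        arc_grid=t.arc_grid.copy(),
        x=x,
        y=y,
        fps=t.fps,
        body_length=t.body_length,
    )


def velocities(c: CenterlineSeries) -> VelocityField:
    """Material-point velocities and the local tangent/normal frame.

    Time derivatives use second-order differences on the actual time stamps
    (``np.gradient`` with the coordinate array handles non-uniform steps with
    per-step stencils; one-sided second order at the first/last frame).
    """
    if c.n_frames < 3:
        raise InsufficientDataError("need >= 3 frames for velocity estimation")
    u_x = np.gradient(c.x, c.times, axis=0, edge_order=2)
    u_y = np.gradient(c.y, c.times, axis=0, edge_order=2)

    dxds = np.gradient(c.x, c.arc_grid, axis=1, edge_order=2)
    dyds = np.gradient(c.y, c.arc_grid, axis=1, edge_order=2)
    speed = np.hypot(dxds, dyds)
    if np.any(speed < 1e-9):
        raise GeometryError("zero-length tangent (coincident centerline points)")
    tx, ty = dxds / speed, dyds / speed
    nx, ny = -ty, tx  # +90° rotation of the tangent

    u_t = u_x * tx + u_y * ty
    u_n = u_x * nx + u_y * ny
    return VelocityField(
        u_x=u_x,
        u_y=u_y,
        u_t=u_t,
        u_n=u_n,
        t_hat=np.stack([tx, ty], axis=-1),
        n_hat=np.stack([nx, ny], axis=-1),
        arc_grid=c.arc_grid.copy(),
        times=c.times.copy(),
    )


# ---------------------------------------------------------------------------
# resampling of raw polylines
# ---------------------------------------------------------------------------


def resample_polyline(
    xy: np.ndarray, arc_grid: np.ndarray, smoothing: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a raw polyline onto a uniform arc-length grid.

    A cubic (smoothing) spline is fitted to x and y against cumulative chord
    length; the spline's arc length is then measured on a fine subdivision and
    inverted so that the output points are equally spaced *along the curve*,
    not merely along the chord parameter.

    Parameters
    ----------
    xy : (P, 2) array
        Raw digitised points, ordered from head to tip, P >= 5.
    arc_grid : (M,) array
        Target uniform arc grid spanning [0, L].
    smoothing : float
        Spline smoothing factor (scipy ``splrep`` ``s`` parameter, μm²);
        0 interpolates the raw points exactly.

    Returns
    -------
    (x, y) : two (M,) arrays of resampled positions.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 5:
        raise InsufficientDataError("polyline must be (P, 2) with P >= 5")
    chord = np.concatenate(([0.0], np.cumsum(np.hypot(*np.diff(xy, axis=0).T))))
    if np.any(np.diff(chord) <= 0):
        raise GeometryError("coincident points in raw polyline")
    tck_x = splrep(chord, xy[:, 0], k=3, s=smoothing)
    tck_y = splrep(chord, xy[:, 1], k=3, s=smoothing)
    # measure spline arc length on a fine subdivision
    tf = np.linspace(0.0, chord[-1], 20 * xy.shape[0])
    xf, yf = splev(tf, tck_x), splev(tf, tck_y)
    arc = np.concatenate(([0.0], np.cumsum(np.hypot(np.diff(xf), np.diff(yf)))))
    # invert arc(t): target arc positions scaled to the measured total length
    target = arc_grid / arc_grid[-1] * arc[-1]
    t_of_s = np.interp(target, arc, tf)
    return np.asarray(splev(t_of_s, tck_x)), np.asarray(splev(t_of_s, tck_y))


def resample_series(
    frames_xy: list[np.ndarray],
    times: np.ndarray,
    n_points: int = 100,
    body_length: float | None = None,
    fps: float = 400.0,
    smoothing: float = 0.0,
) -> CenterlineSeries:
    """Build a :class:`CenterlineSeries` from per-frame raw polylines of
    possibly unequal length.  ``body_length`` defaults to the median measured
    spline arc length across frames."""
    if body_length is None:
        lengths = []
        for xy in frames_xy:
            xy = np.asarray(xy, dtype=float)
            lengths.append(np.hypot(*np.diff(xy, axis=0).T).sum())
        body_length = float(np.median(lengths))
    arc_grid = np.linspace(0.0, body_length, n_points)
    xs, ys = [], []
    for xy in frames_xy:
        xr, yr = resample_polyline(np.asarray(xy, dtype=float), arc_grid, smoothing)
        xs.append(xr)
        ys.append(yr)
    return CenterlineSeries(
        times=np.asarray(times, dtype=float),
        arc_grid=arc_grid,
        x=np.vstack(xs),
        y=np.vstack(ys),
        fps=fps,
        body_length=body_length,
    )
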