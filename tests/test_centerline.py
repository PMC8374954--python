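"""Geometry core: tangent angles, reconstruction, velocities, resampling."""

import numpy as np
import pytest

import flagkin as fk
from flagkin.centerline import resample_polyline, resample_series
from flagkin.errors import DataError, GeometryError, InsufficientDataError

from conftest import sinusoid_series


def make_series(psi_fn, n_frames=50, m=100, L=110.0, fps=400.0):
    times = np.arange(n_frames) / fps
    arc = np.linspace(0.0, L, m)
    psi = psi_fn(arc[None, :], times[:, None])
    t = fk.TangentAngleField(psi=np.broadcast_to(psi, (n_frames, m)).copy(),
                             arc_grid=arc, times=times, fps=fps, body_length=L)
    return fk.reconstruct_centerline(t)


class TestTangentAngles:
    def test_straight_horizontal_filament_has_zero_angle(self, straight_series):
        psi = fk.tangent_angles(straight_series).psi
        assert np.allclose(psi, 0.0, atol=1e-12)

    def test_quarter_circle_arc_angle_is_linear_in_arclength(self):
        # ψ(s) = s/R for a circle of radius R traversed from angle 0
        R = 110.0 * 2 / np.pi  # quarter circle of length 110
        arc = np.linspace(0.0, 110.0, 200)
        times = np.arange(5) / 400.0
        theta = arc / R
        x = np.tile(R * np.sin(theta), (5, 1))
        y = np.tile(R * (1 - np.cos(theta)), (5, 1))
        c = fk.CenterlineSeries(times, arc, x, y)
        psi = fk.tangent_angles(c).psi
        assert np.abs(psi - theta[None, :]).max() < 1e-3

    def test_roundtrip_through_reconstruction(self, default_wave):
        series, _ = default_wave
        t = fk.tangent_angles(series)
        back = fk.reconstruct_centerline(t, head_xy=(series.x[0, 0], series.y[0, 0]))
        # identity up to rigid translation; head is common so direct compare
        err = np.hypot(back.x - series.x, back.y - series.y).max()
        assert err < 0.1

    def test_coincident_points_raise_geometry_error(self, straight_series):
        s = straight_series
        x = s.x.copy()
        x[:, 10] = x[:, 11]  # duplicate a point: zero-length segment
        x[:, 9] = x[:, 11]
        bad = fk.CenterlineSeries(s.times, s.arc_grid, x, s.y)
        with pytest.raises(GeometryError):
            fk.tangent_angles(bad)

    def test_unwrapped_along_arc(self, default_wave):
        series, _ = default_wave
        psi = fk.tangent_angles(series).psi
        assert np.abs(np.diff(psi, axis=1)).max() < np.pi

    def test_branch_continuous_in_time(self, default_wave):
        series, _ = default_wave
        psi = fk.tangent_angles(series).psi
        assert np.abs(np.diff(psi[:, 0])).max() < np.pi


class TestReconstruction:
    def test_zero_angle_gives_horizontal_segment(self):
        c = make_series(lambda s, t: np.zeros_like(s + t))
        assert np.allclose(c.x[:, -1], 110.0) and np.allclose(c.y, 0.0)

    def test_right_angle_gives_vertical_segment(self):
        c = make_series(lambda s, t: np.full_like(s + t, np.pi / 2))
        assert np.allclose(c.y[:, -1], 110.0) and np.allclose(c.x, 0.0, atol=1e-10)

    def test_arc_length_preserved_for_random_smooth_shapes(self):
        rng = np.random.default_rng(42)
        coefs = rng.normal(0, 0.3, 5)
        c = make_series(
            lambda s, t: sum(a * np.sin((j + 1) * np.pi * s / 110.0) for j, a in enumerate(coefs))
            + 0 * t
        )
        lengths = np.hypot(np.diff(c.x, axis=1), np.diff(c.y, axis=1)).sum(axis=1)
        assert np.abs(lengths - 110.0).max() / 110.0 < 0.005


class TestVelocities:
    def test_rigid_translation(self):
        times = np.arange(50) / 400.0
        arc = np.linspace(0.0, 110.0, 100)
        x = arc[None, :] + 10.0 * times[:, None]
        y = np.zeros_like(x)
        v = fk.velocities(fk.CenterlineSeries(times, arc, x, y))
        assert np.allclose(v.u_x, 10.0) and np.allclose(v.u_y, 0.0)
        # horizontal filament: all motion is tangential
        assert np.allclose(v.u_t, 10.0) and np.allclose(v.u_n, 0.0, atol=1e-9)

    def test_stationary_filament(self, straight_series):
        v = fk.velocities(straight_series)
        for a in (v.u_x, v.u_y, v.u_t, v.u_n):
            assert np.allclose(a, 0.0)

    def test_transverse_wave_normal_velocity_matches_analytic(self):
        A, f = 0.5, 7.0
        c = sinusoid_series(A=A, f_hz=f, n_frames=400)
        v = fk.velocities(c)
        om = 2 * np.pi * f
        k = 2 * np.pi / 110.0
        expected = -A * om * np.cos(k * c.arc_grid[None, :] - om * c.times[:, None])
        interior = np.s_[2:-2, :]
        err = np.abs(v.u_n[interior] - expected[interior]).max() / (A * om)
        assert err < 0.01

    def test_orthonormal_frame_reconstructs_velocity(self, default_wave):
        series, _ = default_wave
        v = fk.velocities(series)
        ux = v.u_t * v.t_hat[..., 0] + v.u_n * v.n_hat[..., 0]
        uy = v.u_t * v.t_hat[..., 1] + v.u_n * v.n_hat[..., 1]
        assert np.abs(ux - v.u_x).max() < 1e-9 * max(1, np.abs(v.u_x).max())
        assert np.abs(uy - v.u_y).max() < 1e-9 * max(1, np.abs(v.u_y).max())
        norms_t = np.linalg.norm(v.t_hat, axis=-1)
        assert np.allclose(norms_t, 1.0)
        assert np.allclose((v.t_hat * v.n_hat).sum(-1), 0.0, atol=1e-14)

    def test_time_integral_of_velocity_recovers_displacement(self, default_wave):
        from scipy.integrate import cumulative_trapezoid

        series, _ = default_wave
        v = fk.velocities(series)
        x_rec = series.x[0] + cumulative_trapezoid(v.u_x, series.times, axis=0, initial=0.0)
        scale = np.abs(series.x - series.x[0]).max()
        assert np.abs(x_rec[-1] - series.x[-1]).max() < 0.01 * max(scale, 1.0)

    def test_frame_rotation_rotates_vectors_but_not_components(self, default_wave):
        series, _ = default_wave
        phi = 0.7
        ca, sa = np.cos(phi), np.sin(phi)
        rot = fk.CenterlineSeries(
            series.times, series.arc_grid,
            ca * series.x - sa * series.y, sa * series.x + ca * series.y,
            fps=series.fps, body_length=series.body_length,
        )
        v0, v1 = fk.velocities(series), fk.velocities(rot)
        assert np.abs(v1.u_t - v0.u_t).max() < 1e-8
        assert np.abs(v1.u_n - v0.u_n).max() < 1e-8
        tx = ca * v0.t_hat[..., 0] - sa * v0.t_hat[..., 1]
        assert np.abs(v1.t_hat[..., 0] - tx).max() < 1e-12


class TestValidation:
    def test_validate_accepts_clean_series(self, default_wave):
        series, _ = default_wave
        assert series.validate() is series

    def test_validate_rejects_nonmonotone_time(self, straight_series):
        s = straight_series
        times = s.times.copy()
        times[5] = times[4]
        with pytest.raises(DataError):
            fk.CenterlineSeries(times, s.arc_grid, s.x, s.y).validate()

    def test_validate_rejects_too_few_frames(self):
        arc = np.linspace(0, 110, 100)
        c = fk.CenterlineSeries(np.arange(2) / 400, arc, np.tile(arc, (2, 1)), np.zeros((2, 100)))
        with pytest.raises(InsufficientDataError):
            c.validate()

    def test_validate_rejects_untethered_head(self, straight_series):
        s = straight_series
        x = s.x + 10.0 * np.sin(2 * np.pi * s.times)[:, None]  # head drifts ~10 μm
        with pytest.raises(DataError):
            fk.CenterlineSeries(s.times, s.arc_grid, x, s.y).validate()


class TestResampling:
    def test_resampled_polyline_matches_spline_arclength(self):
        rng = np.random.default_rng(7)
        # wiggly raw polyline with irregular spacing, 80-120 points
        raw_t = np.sort(rng.uniform(0, 1, rng.integers(80, 121)))
        raw_t[0], raw_t[-1] = 0.0, 1.0
        x = 110 * raw_t
        y = 8 * np.sin(2 * np.pi * raw_t) + 3 * np.sin(5 * np.pi * raw_t)
        arc_grid = np.linspace(0, 110, 100)
        xr, yr = resample_polyline(np.column_stack([x, y]), arc_grid)
        chords = np.hypot(np.diff(xr), np.diff(yr))
        ds = np.diff(arc_grid)
        # resampled grid is scaled to the measured curve length, so chord
        # spacing is compared to its own mean, not to the nominal grid step
        assert np.abs(chords - chords.mean()).max() / chords.mean() < 0.02
        total = chords.sum()
        naive = np.hypot(np.diff(x), np.diff(y)).sum()
        assert total >= naive * 0.999  # spline length >= polyline length

    def test_resample_series_builds_valid_uniform_grid(self):
        rng = np.random.default_rng(3)
        frames = []
        for i in range(5):
            n = rng.integers(80, 121)
            t = np.linspace(0, 1, n)
            frames.append(np.column_stack([110 * t, 5 * np.sin(2 * np.pi * t + 0.1 * i)]))
        c = resample_series(frames, np.arange(5) / 400.0, n_points=100)
        assert c.n_points == 100
        c.validate(tethered=False)
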