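"""Beat kinematics: POF estimation, cycle segmentation, representative
cycle averaging, amplitude envelope, regional partition."""

import numpy as np
import pytest

import flagkin as fk
from flagkin.errors import (
    DegeneratePhaseError,
    InsufficientCyclesError,
    InsufficientDataError,
    NoOscillationError,
)
from flagkin.kinematics import BeatCycle

from conftest import sinusoid_series


class TestPOF:
    @pytest.mark.parametrize("f", [3.0, 5.0, 7.0, 9.0])
    def test_pure_sinusoid_recovered_to_sub_bin_accuracy(self, f):
        t = np.arange(1000) / 400.0
        res = fk.primary_oscillation_frequency(np.sin(2 * np.pi * f * t), 400.0)
        assert res.pof_hz == pytest.approx(f, abs=0.1)

    def test_constant_series_has_no_oscillation(self):
        with pytest.raises(NoOscillationError):
            fk.primary_oscillation_frequency(np.full(512, 2.5), 400.0)

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            fk.primary_oscillation_frequency(np.sin(np.arange(100)), 400.0)

    def test_dominant_peak_wins_over_secondary_tone(self):
        t = np.arange(1000) / 400.0
        series = np.sin(2 * np.pi * 5 * t) + 0.3 * np.sin(2 * np.pi * 10 * t)
        res = fk.primary_oscillation_frequency(series, 400.0)
        assert res.pof_hz == pytest.approx(5.0, abs=0.1)

    def test_b2_consistency_flag(self):
        t = np.arange(1000) / 400.0
        b1 = np.sin(2 * np.pi * 7 * t)
        assert fk.primary_oscillation_frequency(b1, 400.0, np.cos(2 * np.pi * 7 * t)).b2_consistent
        res = fk.primary_oscillation_frequency(b1, 400.0, np.sin(2 * np.pi * 11 * t))
        assert res.b2_consistent is False

    def test_pipeline_recovery_from_generator(self, default_wave, default_decomposition):
        series, truth = default_wave
        d = default_decomposition
        res = fk.primary_oscillation_frequency(d.coeffs[:, 0], series.fps, d.coeffs[:, 1])
        assert res.pof_hz == pytest.approx(truth["frequency_hz"], abs=0.1)


class TestSegmentation:
    def test_circular_b_space_loop_counts_cycles(self):
        t = np.arange(1000) / 400.0  # 2.5 s at 7 Hz -> 17.5 cycles
        cycles = fk.segment_beat_cycles(
            np.cos(2 * np.pi * 7 * t), np.sin(2 * np.pi * 7 * t), t
        )
        assert len(cycles) in (16, 17)
        periods = [c.period for c in cycles]
        assert np.allclose(periods, 1 / 7.0, rtol=1e-3)

    def test_reversed_loop_direction_also_segments(self):
        t = np.arange(1000) / 400.0
        cycles = fk.segment_beat_cycles(
            np.cos(2 * np.pi * 7 * t), -np.sin(2 * np.pi * 7 * t), t
        )
        assert len(cycles) in (16, 17)

    def test_one_dimensional_oscillation_is_degenerate(self):
        t = np.arange(1000) / 400.0
        with pytest.raises(DegeneratePhaseError):
            fk.segment_beat_cycles(np.cos(2 * np.pi * 7 * t), np.zeros_like(t), t)

    def test_too_short_record_raises(self):
        t = np.arange(300) / 400.0  # 0.75 s at 2 Hz -> 1 complete cycle
        with pytest.raises(InsufficientCyclesError):
            fk.segment_beat_cycles(np.cos(2 * np.pi * 2 * t), np.sin(2 * np.pi * 2 * t), t)

    def test_noisy_beat_cycle_count_near_truth(self):
        rng = np.random.default_rng(5)
        t = np.arange(1000) / 400.0
        b1 = np.cos(2 * np.pi * 7 * t) + 0.1 * rng.standard_normal(1000)
        b2 = np.sin(2 * np.pi * 7 * t) + 0.1 * rng.standard_normal(1000)
        cycles = fk.segment_beat_cycles(b1, b2, t)
        assert abs(len(cycles) - 17) <= 1


class TestAverageCycle:
    def _cycles(self, series):
        d = fk.pod_decompose(fk.tangent_angles(series))
        return fk.segment_beat_cycles(d.coeffs[:, 0], d.coeffs[:, 1], series.times)

    def test_periodic_beat_has_negligible_dispersion(self, default_wave):
        series, _ = default_wave
        avg = fk.average_beat_cycle(series, self._cycles(series))
        assert avg.sd_x.max() < 1e-6 * series.body_length
        assert avg.sd_y.max() < 1e-6 * series.body_length

    def test_dispersion_tracks_injected_noise(self):
        series, _ = fk.generate_traveling_wave(fk.WaveSpec(noise_sigma=0.2, seed=12))
        avg = fk.average_beat_cycle(series, self._cycles(series))
        # per-coordinate SD ≈ σ√2 (head-position subtraction in the body
        # frame adds an independent σ² to every point), and combining the
        # two coordinates gives hypot ≈ 2σ = 0.4 μm
        mean_sd = np.mean(np.hypot(avg.sd_x, avg.sd_y)[:, 1:])
        assert 0.75 * 2 * 0.2 < mean_sd < 1.25 * 2 * 0.2

    def test_average_matches_single_cycle_for_clean_input(self, default_wave):
        series, _ = default_wave
        cycles = self._cycles(series)
        avg_all = fk.average_beat_cycle(series, cycles)
        avg_three = fk.average_beat_cycle(series, cycles[:3])
        dev = np.hypot(avg_all.mean_x - avg_three.mean_x, avg_all.mean_y - avg_three.mean_y)
        assert dev.max() < 0.2

    def test_phase_grid_refinement_stable(self, default_wave):
        series, _ = default_wave
        cycles = self._cycles(series)
        a64 = fk.flagellar_amplitude(fk.average_beat_cycle(series, cycles, 64))
        a128 = fk.flagellar_amplitude(fk.average_beat_cycle(series, cycles, 128))
        ref = a64.amplitude.max()
        assert np.abs(a64.amplitude - a128.amplitude).max() < 0.01 * ref

    def test_rotation_invariance_of_body_frame_average(self, default_wave):
        series, _ = default_wave
        phi = 1.1
        ca, sa = np.cos(phi), np.sin(phi)
        rot = fk.CenterlineSeries(
            series.times, series.arc_grid,
            ca * series.x - sa * series.y, sa * series.x + ca * series.y,
            fps=series.fps, body_length=series.body_length,
        )
        a0 = fk.average_beat_cycle(series, self._cycles(series))
        a1 = fk.average_beat_cycle(rot, self._cycles(rot))
        assert np.abs(a0.mean_x - a1.mean_x).max() < 1e-6
        assert np.abs(a0.mean_y - a1.mean_y).max() < 1e-6


class TestAmplitude:
    def test_static_filament_would_have_zero_amplitude(self):
        # a straight, non-beating filament: build the average directly
        arc = np.linspace(0, 110, 50)
        flat = np.tile(arc, (16, 1))
        avg = fk.BeatCycleAverage(
            phase_grid=np.arange(16) / 16.0, mean_x=flat, mean_y=np.zeros_like(flat),
            sd_x=np.zeros_like(flat), sd_y=np.zeros_like(flat),
            period=0.1, n_cycles=5, arc_grid=arc,
        )
        assert np.allclose(fk.flagellar_amplitude(avg).amplitude, 0.0)

    def test_positional_wave_amplitude_recovered(self):
        # head-clamped transverse wave: y = w(s)·A·sin(ks − ωt) with a
        # proximal ramp w tethering the head, so the body frame is static
        A, f = 5.0, 7.0
        times = np.arange(1000) / 400.0
        arc = np.linspace(0.0, 110.0, 100)
        w = np.minimum(arc / 20.0, 1.0)
        k, om = 2 * np.pi / 110.0, 2 * np.pi * f
        x = np.tile(arc, (1000, 1))
        y = w[None, :] * A * np.sin(k * arc[None, :] - om * times[:, None])
        series = fk.CenterlineSeries(times, arc, x, y)
        d = fk.pod_decompose(fk.tangent_angles(series))
        cycles = fk.segment_beat_cycles(d.coeffs[:, 0], d.coeffs[:, 1], series.times)
        amp = fk.flagellar_amplitude(fk.average_beat_cycle(series, cycles))
        away = series.arc_grid > 30
        assert np.abs(amp.amplitude[away] * 110.0 - A).max() / A < 0.05

    def test_amplitude_linear_in_generator_amplitude(self):
        amps = {}
        for scale in (0.1, 0.2):
            series, _ = fk.generate_traveling_wave(
                fk.WaveSpec(envelope_base=0.0, envelope_tip=scale)
            )
            d = fk.pod_decompose(fk.tangent_angles(series))
            cycles = fk.segment_beat_cycles(d.coeffs[:, 0], d.coeffs[:, 1], series.times)
            amps[scale] = fk.flagellar_amplitude(fk.average_beat_cycle(series, cycles))
        away = amps[0.1].arc_grid > 20
        ratio = amps[0.2].amplitude[away] / amps[0.1].amplitude[away]
        assert np.abs(ratio - 2.0).max() < 0.04


class TestRegionalSummary:
    def test_constant_profile(self):
        arc = np.linspace(0, 110, 100)
        assert fk.regional_summary(arc, np.full(100, 3.3)) == pytest.approx((3.3, 3.3, 3.3))

    def test_linear_ramp_closed_form(self):
        arc = np.linspace(0, 110, 100)
        mids = fk.regional_summary(arc, arc / 110.0)
        assert mids == pytest.approx((12 / 110, 64 / 110, 107 / 110), rel=1e-9)

    def test_regional_integrals_partition_total(self, default_wave, rft_params):
        series, _ = default_wave
        pw = fk.power_fields(fk.velocities(series), rft_params)
        parts = fk.regional_summary(
            pw.arc_grid * 1e-6, pw.p_bar, (24e-6, 104e-6), integrate=True
        )
        assert sum(parts) == pytest.approx(pw.E, rel=1e-9)

    def test_bad_boundaries_rejected(self):
        arc = np.linspace(0, 110, 100)
        with pytest.raises(fk.errors.ParameterError):
            fk.regional_summary(arc, arc, (104.0, 24.0))
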