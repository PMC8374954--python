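import numpy as np
import pytest

import flagkin as fk


@pytest.fixture(scope="session")
def default_wave():
    """Default mouse-like traveling-wave beat (7 Hz, 400 fps, 1000 frames)."""
    series, truth = fk.generate_traveling_wave(fk.WaveSpec())
    return series, truth


@pytest.fixture(scope="session")
def default_decomposition(default_wave):
    series, _ = default_wave
    return fk.pod_decompose(fk.tangent_angles(series))


@pytest.fixture(scope="session")
def rft_params():
    return fk.RFTParameters()


@pytest.fixture()
def straight_series():
    """Static straight horizontal filament on the default grids."""
    times = np.arange(200) / 400.0
    arc = np.linspace(0.0, 110.0, 100)
    x = np.tile(arc, (200, 1))
    y = np.zeros_like(x)
    return fk.CenterlineSeries(times, arc, x, y)


def sinusoid_series(A=1.0, f_hz=8.0, wavelength=110.0, n_frames=801, fps=400.0, m=100, L=110.0):
    """Small-amplitude positional wave y = A sin(ks - ωt) on a straight backbone.

    Not exactly unit-speed, so it is built directly (bypassing validation);
    adequate for A·k << 1 analytic comparisons.
    """
    times = np.arange(n_frames) / fps
    arc = np.linspace(0.0, L, m)
    k = 2 * np.pi / wavelength
    om = 2 * np.pi * f_hz
    x = np.tile(arc, (n_frames, 1))
    y = A * np.sin(k * arc[None, :] - om * times[:, None])
    return fk.CenterlineSeries(times, arc, x, y, fps=fps, body_length=L)
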