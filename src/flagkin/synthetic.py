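"""Synthetic head-tethered flagellar beats with known ground truth.

The generator emulates the tethered-cell assay geometry — planar beating of
a 110 μm mouse sperm flagellum recorded at 400 frames/s for 1,000 frames —
by prescribing the tangent-angle field directly:

    traveling wave:  ψ(s, τ) = ψ0(s) + ε(s) · sin(2πf·τ − 2πs/λ + φ0)
    standing wave:   ψ(s, τ) = ψ0(s) + ε(s) · sin(2πs/λ) · sin(2πf·τ)

and reconstructing the centerline with the head fixed at the origin.  The
amplitude envelope ε(s) defaults to a linear ramp from a small clamp value at
the head to its tip value, mimicking the increase of beating amplitude along
the tail; with the default tip envelope of 1 rad the tip's lateral excursion
is mouse-like (~15 μm).  The standing wave is reciprocal by construction and
serves as the scallop-theorem control for the free-swimming projection.

Optional i.i.d. Gaussian position noise models centerline-tracking error.
Every stochastic path is driven by the spec's seed, so identical seeds give
bitwise-identical series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .centerline import CenterlineSeries, TangentAngleField, reconstruct_centerline
from .errors import ParameterError

__all__ = [
    "WaveSpec",
    "SyntheticCell",
    "generate_traveling_wave",
    "generate_standing_wave",
    "generate_group",
]


@dataclass
class WaveSpec:
    """Ground-truth parameters of a synthetic beat.

    frequency : Hz, beat frequency (default 7, mouse-like)
    wavelength : μm, wavelength of the tangent-angle wave (default 110)
    envelope_base, envelope_tip : rad, linear amplitude ramp ε(0), ε(L)
    amplitude_envelope : optional (M,) table overriding the linear ramp
    mean_shape : optional (M,) mean tangent-angle profile ψ0 (default 0)
    phase0 : rad, wave phase at s=0, τ=0
    fps, n_frames : acquisition emulation (default 400 fps, 1000 frames)
    n_points, body_length : arc grid (default 100 points over 110 μm)
    noise_sigma : μm, i.i.d. Gaussian tracking noise on positions (default 0)
    seed : RNG seed for the noise
    """

    frequency: float = 7.0
    wavelength: float = 110.0
    envelope_base: float = 0.1
    envelope_tip: float = 1.0
    amplitude_envelope: np.ndarray | None = None
    mean_shape: np.ndarray | None = None
    phase0: float = 0.0
    fps: float = 400.0
    n_frames: int = 1000
    n_points: int = 100
    body_length: float = 110.0
    noise_sigma: float = 0.0
    seed: int = 0

    def grids(self) -> tuple[np.ndarray, np.ndarray]:
        times = np.arange(self.n_frames) / self.fps
        arc = np.linspace(0.0, self.body_length, self.n_points)
        return times, arc

    def envelope(self, arc: np.ndarray) -> np.ndarray:
        if self.amplitude_envelope is not None:
            env = np.asarray(self.amplitude_envelope, dtype=float)
            if env.shape != arc.shape:
                raise ParameterError("amplitude_envelope length must match n_points")
        else:
            env = self.envelope_base + (self.envelope_tip - self.envelope_base) * arc / arc[-1]
        if np.any(env < 0):
            raise ParameterError("amplitude envelope must be non-negative")
        return env

    def validate(self) -> "WaveSpec":
        if self.frequency >= self.fps / 2.0:
            raise ParameterError(
                f"aliasing: frequency {self.frequency} Hz >= Nyquist {self.fps / 2} Hz"
            )
        if min(self.frequency, self.wavelength, self.fps, self.body_length) <= 0:
            raise ParameterError("frequency, wavelength, fps, body_length must be positive")
        if self.n_frames < 3 or self.n_points < 5:
            raise ParameterError("need >= 3 frames and >= 5 points")
        return self


@dataclass
class SyntheticCell:
    """One generated cell with its provenance."""

    cell_id: str
    group: str
    mouse_id: str
    series: CenterlineSeries
    truth: dict = field(default_factory=dict)


def _finalise(spec: WaveSpec, psi: np.ndarray, times: np.ndarray, arc: np.ndarray,
              kind: str) -> tuple[CenterlineSeries, dict]:
    t = TangentAngleField(psi=psi, arc_grid=arc, times=times,
                          fps=spec.fps, body_length=spec.body_length)
    c = reconstruct_centerline(t, head_xy=(0.0, 0.0))
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        c.x = c.x + rng.normal(0.0, spec.noise_sigma, c.x.shape)
        c.y = c.y + rng.normal(0.0, spec.noise_sigma, c.y.shape)
    truth = {
        "kind": kind,
        "frequency_hz": spec.frequency,
        "wavelength_um": spec.wavelength,
        "envelope_rad": spec.envelope(arc),
        "phase0_rad": spec.phase0,
        "noise_sigma_um": spec.noise_sigma,
        "seed": spec.seed,
    }
    return c, truth


def generate_traveling_wave(spec: WaveSpec) -> tuple[CenterlineSeries, dict]:
    """Head-tethered traveling-wave beat; returns (series, ground truth)."""
    spec.validate()
    times, arc = spec.grids()
    env = spec.envelope(arc)
    psi0 = np.zeros_like(arc) if spec.mean_shape is None else np.asarray(spec.mean_shape, float)
    phase = 2 * np.pi * spec.frequency * times[:, None] - 2 * np.pi * arc[None, :] / spec.wavelength
    psi = psi0[None, :] + env[None, :] * np.sin(phase + spec.phase0)
    return _finalise(spec, psi, times, arc, "traveling")


def generate_standing_wave(spec: WaveSpec) -> tuple[CenterlineSeries, dict]:
    """Reciprocal standing-wave beat (scallop-theorem control)."""
    spec.validate()
    times, arc = spec.grids()
    env = spec.envelope(arc)
    psi0 = np.zeros_like(arc) if spec.mean_shape is None else np.asarray(spec.mean_shape, float)
    shape = np.sin(2 * np.pi * arc / spec.wavelength + spec.phase0)
    osc = np.sin(2 * np.pi * spec.frequency * times)
    psi = psi0[None, :] + env[None, :] * shape[None, :] * osc[:, None]
    return _finalise(spec, psi, times, arc, "standing")


def generate_group(
    spec: WaveSpec,
    n_cells: int,
    jitter: float = 0.03,
    seed: int = 0,
    *,
    group: str = "wt",
    n_mice: int = 6,
    kind: str = "traveling",
) -> list[SyntheticCell]:
    """Generate a labelled group of cells with between-cell variability.

    Each cell's frequency and envelope scale are jittered multiplicatively by
    independent Gaussian factors ``1 + jitter·z`` (clipped at 0.2 to stay
    physical); cells are assigned round-robin to ``n_mice`` mouse IDs,
    emulating a 25–30 sperm / 5–6 mice sampling design.  Everything is
    reproducible from ``seed``.
    """
    if n_cells < 2:
        raise ParameterError("need >= 2 cells per group")
    if kind not in ("traveling", "standing"):
        raise ParameterError(f"unknown wave kind {kind!r}")
    gen = generate_traveling_wave if kind == "traveling" else generate_standing_wave
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(2 * n_cells) % (2**31)
    rng = np.random.default_rng(ss.spawn(1)[0])
    cells = []
    for i in range(n_cells):
        f_factor = max(0.2, 1.0 + jitter * rng.standard_normal())
        a_factor = max(0.2, 1.0 + jitter * rng.standard_normal())
        cell_spec = replace(
            spec,
            frequency=spec.frequency * f_factor,
            envelope_base=spec.envelope_base * a_factor,
            envelope_tip=spec.envelope_tip * a_factor,
            amplitude_envelope=(
                None
                if spec.amplitude_envelope is None
                else np.asarray(spec.amplitude_envelope) * a_factor
            ),
            phase0=float(2 * np.pi * i / n_cells),
            seed=int(cell_seeds[i]),
        )
        series, truth = gen(cell_spec)
        cells.append(
            SyntheticCell(
                cell_id=f"{group}_{i:03d}",
                group=group,
                mouse_id=f"{group}_m{i % n_mice + 1}",
                series=series,
                truth=truth,
            )
        )
    return cells
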