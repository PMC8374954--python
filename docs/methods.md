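# Methods

This note records the models, numerical choices and known limitations of
`flagkin`, in the spirit of a methods section: what is computed, under
which assumptions, and what the tests do and do not demonstrate.

## Data model and geometry

A cell is a `CenterlineSeries`: positions x(s, τ), y(s, τ) in μm on a
uniform arc-length grid (default M = 100 points from s = 0 at the head/neck
junction to s = L = 110 μm at the tip) and strictly increasing frame times
(nominally 1/fps apart at fps = 400). The grid size M is a numerical
choice, not a measurement property: a uniform grid keeps quadrature simple
and makes shape modes comparable across cells. Raw digitised polylines of
unequal length are resampled at read time with a cubic (optionally
smoothing) spline parameterised by chord length; the spline's own arc
length is measured on a 20× subdivision and inverted, so resampled points
are equally spaced along the curve, with chord spacing uniform to better
than 2%. Validation enforces monotone grids, finite values, chord
uniformity, and — for tethered data — a head excursion below 2 μm.
z-coordinates are rejected outright: the analysis is strictly planar and
silently dropping a dimension would hide a modelling error.

The tangent angle ψ = atan2(∂y/∂s, ∂x/∂s) uses second-order central
differences (one-sided second order at the ends), is unwrapped along s
within each frame, and is made branch-continuous in time by removing whole
2π jumps of the *frame-mean* angle between consecutive frames. Anchoring
on the mean rather than the head point is deliberate: tracking noise passed
through the one-sided end stencil can flip a single point's angle by ~π,
and an anchor on one noisy point occasionally misclassifies that as a
branch jump, poisoning every later frame; the frame mean is √M times
quieter and the 2π decision is then unambiguous at realistic noise levels.

Centerline reconstruction from ψ is cumulative trapezoidal quadrature of
(cos ψ, sin ψ); the round trip through tangent angles and back is accurate
to < 0.1 μm for smooth 110 μm shapes at M = 100, and reconstructed arc
length is preserved to 0.5%.

Material-point velocities use `np.gradient` on the actual time stamps —
second-order per-step stencils that remain valid for non-uniform sampling —
with one-sided second-order stencils at the first and last frame. The
local frame (t̂, n̂ = t̂ rotated +90°) is orthonormal by construction, so
u_t t̂ + u_n n̂ reassembles (u_x, u_y) exactly.

## Shape-mode decomposition

POD demeans over time only (ψ0 is the columnwise time average; no per-point
variance normalisation) and takes the modes from the SVD of the deviation
matrix, which is algebraically the eigendecomposition of the covariance
XᵀX — the test suite checks the two routes against each other on small
random fields. SVD leaves each mode's sign arbitrary; the largest-|entry|
element of every mode is made positive (ties broken by first index), which
makes decompositions bitwise reproducible and comparable across cells.
Nearly tied singular values (relative gap < 1e-6) are flagged as degenerate
pairs, because within such a pair the mode plane is rotationally ambiguous
and per-mode variance splits are arbitrary; `variance_explained` warns when
asked to split a flagged pair. A field whose total deviation energy is at
the level of rounding in the time mean is reported as the zero-variance
(static) case with all variance fractions zero rather than normalising
numerical dust. The full decomposition is always computed; reporting
defaults to four modes.

## Beat frequency (POF)

The POF is the dominant peak of the de-meaned B1 power spectrum inside
(0.5 Hz, Nyquist), refined by fitting a parabola to the log-power of the
three bins around the maximum. The series is Hann-windowed first: with a
rectangular window the three-bin log-parabola has a bin-offset bias of up
to ~0.2 bin, which at the 0.4 Hz resolution of a 2.5 s record would not
reliably deliver ±0.1 Hz; with the Hann window the interpolation bias is
two orders of magnitude below that. B2 is analysed identically as a
consistency check and the result is flagged if the two peaks differ by more
than one bin. A peak at the search-band edge sets a warning flag; a
constant series raises a no-oscillation error. At least 256 samples are
required.

## Cycle segmentation, representative cycle, amplitude

The beat phase is θ(τ) = atan2(B2/σ_B2, B1/σ_B1); after unwrapping, cycle
boundaries are the linearly interpolated crossings of θ through multiples
of 2π in the loop's dominant direction, partial first/last cycles are
dropped, and at least 3 complete cycles are required. If either
coefficient has (numerically) zero variance the phase is undefined and a
degenerate-phase error is raised rather than guessing.

Before averaging, positions are moved to a body frame: head at the origin
in every frame, and the whole record rotated by one angle per cell so the
time-mean tangent over the proximal 10% of arc length points along +x.
Because the rotation is a single per-cell angle derived from the data, all
body-frame quantities (representative cycle, amplitude, Procrustes
distances, POF, regional summaries) are invariant under lab-frame rotation
and translation. Within each cycle, frames get a linear phase in [0, 1)
and positions are interpolated onto a P-point phase grid (default P = 64)
with a cubic spline in time; linear interpolation would leave an O(Δτ²)
phase-dependent bias (~4e-5 L at 57 frames/cycle) that masquerades as
beat-to-beat dispersion, whereas the spline keeps the dispersion of a
perfectly periodic beat at numerical precision. The per-(phase, arc) SD
across cycles measures true beat-to-beat variability; note that head
subtraction adds the head's own tracking noise to every point, so with
i.i.d. position noise σ the expected per-point SD is ≈ σ√2 per coordinate.

The amplitude envelope is half the peak-to-peak excursion of the body-frame
lateral coordinate over the phase grid, normalised by L (the
representative cycle is averaged first, then normalised). Regional
summaries integrate profiles with the trapezoidal rule over the mouse-sperm
partition mid-piece [0, 24) μm, principal piece [24, 104) μm, end piece
[104, 110] μm, inserting linearly interpolated boundary values so the three
pieces partition the full integral exactly; means are arc-weighted, and
power densities are integrated instead (regional watts) so the regions sum
to the whole-cell rate.

## Resistive-force-theory hydrodynamics

Friction coefficients ζ_t = 2πμ/ln(2h/a), ζ_n = 2ζ_t with the linear taper
a(s) = (a_h − a_t)(L − s)/L + a_t, a_h = 0.57 μm, a_t = 0.18 μm, and wall
distance h fixed at a_h along the whole tail — a physically approximate
but simple near-wall model, implemented as stated with every parameter
exposed. Defaults: μ = 1 mPa·s (1 cP), L = 110 μm. User-facing units are
μm and seconds; conversion to SI happens only inside the hydrodynamics
modules. The dissipation density p = ζ_t u_t² + ζ_n u_n² is non-negative
for any motion; p̄(s) divides the trapezoidal time integral by the record
duration, and E is the trapezoidal arc integral of p̄ (reported in W with a
femtowatt accessor). One-sided boundary-frame velocities are included in
the average by default; `trim_boundary_frames` excludes them. E is exactly
linear in viscosity and exactly quadratic under time compression, and
changes by < 1% under simultaneous 4× refinement of both grids for
band-limited beats.

## Free-swimming projection

Per frame, A(τ) = ∫ζ̂ ds and b(τ) = ∫ζ̂·u ds (trapezoidal in s, SI units);
A is symmetric positive definite for any filament of nonzero length, and
U = −A⁻¹b satisfies the force balance with relative residual below 1e-10.
Only force balance is imposed — the projection yields a translation
velocity; body rotation (torque balance) is neglected, a documented
limitation of the model, not of the implementation. The trajectory is the
cumulative trapezoidal integral of U; VSL is the per-cycle displacement
over the period, averaged over all complete cycles (the single-cycle value
is also reported, since a one-cycle and a multi-cycle definition are both
defensible). Cycle-edge positions are evaluated with a cubic spline
because R oscillates strongly within a cycle and linear interpolation at
the edges would dominate the per-cycle displacement error; with the spline
a reciprocal (standing-wave) beat shows < 1e-3 μm net displacement per
cycle — the numerical scallop theorem.

## Procrustes comparison

Patterns must share the phase and arc grids and the body frame. The
default "rms" variant is the root-mean-square pointwise deviation in μm;
the "sum" variant (plain sum of pointwise Euclidean deviations) is kept
behind a flag. No rotation or scaling superimposition is performed — the
shared body frame *is* the alignment — except that the second pattern's
phase origin is exhaustively shifted over the P-grid and the minimising
shift reported, removing the arbitrary phase offset between independently
segmented recordings. Per-phase-row squared sums are combined with exact
summation (`math.fsum`) so d(a, b) = d(b, a) holds exactly in floating
point. The measure scales linearly with the coordinates; whether inputs
were length-normalised is recorded in the result. Group tables report
within-group and between-group pairwise mean ± SD; singleton groups are
flagged (NaN), not fatal.

## Synthetic waveform generator

The generator prescribes the tangent-angle field directly —
ψ = ψ0 + ε(s)·sin(2πfτ − 2πs/λ + φ0) for a traveling wave,
ψ = ψ0 + ε(s)·sin(2πs/λ)·sin(2πfτ) for a reciprocal standing wave — and
reconstructs positions with the head fixed at the origin (the tether
model: head point fixed, proximal angle free to oscillate). Defaults
emulate the tethered-cell acquisition: f = 7 Hz, λ = 110 μm, fps = 400,
1000 frames, M = 100, and an amplitude envelope ramping linearly from
0.1 rad at the head to 1.0 rad at the tip, which yields a tip lateral
excursion of ~15 μm and a whole-cell dissipation of ~1e2 fW in 1 cP —
mouse-like numbers. Optional i.i.d. Gaussian position noise (seeded)
models centerline-tracking error; temporal noise correlation is not
modelled. Groups jitter each cell's frequency and envelope scale by
multiplicative Gaussian factors (default 3% SD — modest between-cell
variability under which a 25-cell group mean estimates the nominal
frequency with ≈ 0.04 Hz standard error) and assign cells round-robin to
mouse IDs, emulating a 25–30 sperm / 5–6 mice design.

What the generator does *not* emulate: the strong standing-wave and
asymmetric components of real mouse beats, curvature saturation,
hyperactivated (self-crossing) waveforms, and 3D excursions. Consequences
worth stating plainly: a pure traveling wave is an efficient low-Reynolds
swimmer, so the projected VSL of the mouse-like default (~76 μm/s) far
exceeds real mouse sperm projections (a few μm/s) even though its power
dissipation brackets real values; passing tests demonstrate correctness of
the algorithms and scalings, not that synthetic kinematic magnitudes match
real sperm in every quantity.

## Degenerate inputs and tie-breaks

Coincident centerline points raise a geometry error (zero-length tangent).
A static field is a zero-variance decomposition, and downstream frequency
analysis raises a no-oscillation error rather than returning a spurious
peak. One-dimensional B-space motion raises a degenerate-phase error.
Procrustes ties across phase shifts resolve to the smallest shift. The
wall-corrected friction model requires 2h/a > 1 everywhere and rejects
parameters violating it.

## Batch pipeline

Per-cell failures are isolated: a cell violating a precondition is logged
with its reason and skipped; the batch fails only if every cell fails. All
outputs are plain text (TSV/JSON/YAML) with fixed numeric formatting and no
timestamps, so a rerun with identical inputs and configuration is
byte-identical; the configuration used is written next to the outputs for
provenance. Figures (B-space loops, representative cycle, amplitude
envelopes, p̄(s) curves) are optional and headless-safe. Statistical
testing is intentionally out of scope — the tables are export-ready for any
external statistics tool.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on 3–1000 frame records at M = 50–100; the
oracle comparisons for the decomposition use fields up to 20×20 where the
brute-force eigendecomposition is cheap and unambiguous. The end-to-end
check and the acceptance script simulate 2 groups × 25 cells × 1000 frames
× 100 points — the study's own sampling design — which completes in well
under a minute per run on one CPU.
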