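"""Shape-mode decomposition of a synthetic head-tethered beat.

Generates the default mouse-like traveling wave (7 Hz, 110 μm flagellum,
400 fps, 1000 frames), decomposes the tangent-angle field into shape modes,
and reports how much of the movement the leading modes carry and the beat
frequency estimated from the first shape coefficient.
"""

import flagkin as fk

series, truth = fk.generate_traveling_wave(fk.WaveSpec())
decomp = fk.pod_decompose(fk.tangent_angles(series))

print(f"ground-truth beat frequency : {truth['frequency_hz']:.2f} Hz")
print(f"variance in modes 1-2       : {fk.variance_explained(decomp, [1, 2]):.4f}")
print(f"variance in modes 1-4       : {fk.variance_explained(decomp, [1, 2, 3, 4]):.4f}")

pof = fk.primary_oscillation_frequency(decomp.coeffs[:, 0], series.fps, decomp.coeffs[:, 1])
print(f"primary oscillation freq    : {pof.pof_hz:.3f} Hz (B2 consistent: {pof.b2_consistent})")

# A traveling wave is (sin, cos) in time on two spatial profiles, so two
# modes carry essentially all the variance and B1-B2 traces a closed loop
# once per beat; the POF matches the generator's frequency to the sub-bin
# accuracy of the interpolated spectral peak.
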