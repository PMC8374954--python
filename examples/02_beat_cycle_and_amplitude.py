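"""Beat-cycle segmentation, representative cycle, and amplitude envelope.

Segments the record into complete beat cycles from the B1-B2 phase,
averages them into a representative beat pattern, and summarises the
length-normalised beating amplitude over the mid-piece (0-24 μm),
principal piece (24-104 μm) and end piece (104-110 μm).
"""

import flagkin as fk

series, _ = fk.generate_traveling_wave(fk.WaveSpec())
decomp = fk.pod_decompose(fk.tangent_angles(series))
cycles = fk.segment_beat_cycles(decomp.coeffs[:, 0], decomp.coeffs[:, 1], series.times)
avg = fk.average_beat_cycle(series, cycles)
amp = fk.flagellar_amplitude(avg)
regions = fk.regional_summary(amp.arc_grid, amp.amplitude)

print(f"complete beat cycles        : {avg.n_cycles}")
print(f"mean beat period            : {avg.period * 1e3:.2f} ms "
      f"({1 / avg.period:.2f} Hz)")
print(f"max amplitude (fraction L)  : {amp.amplitude.max():.4f} "
      f"= {amp.amplitude.max() * series.body_length:.1f} μm at the tip")
print("regional mean amplitudes    : "
      f"mid {regions[0]:.4f}, principal {regions[1]:.4f}, end {regions[2]:.4f}")
print(f"beat-to-beat dispersion     : max SD {max(avg.sd_x.max(), avg.sd_y.max()):.2e} μm")

# The amplitude grows along the tail (the generator ramps the tangent-angle
# envelope), is zero at the tethered head, and the noise-free beat repeats
# so exactly that the across-cycle dispersion is at numerical precision.
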