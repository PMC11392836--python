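"""From a parcel time series to a Welch power spectrum.

Simulates 60 s of colored noise with an alpha oscillation at 10 Hz, applies
the 5-s segmentation rule (at least 10 segments), and estimates the PSD
with Hamming windows at 80% overlap -- giving the 0.2 Hz grid the peak
fitting stage expects.
"""

import numpy as np

import alphapeak as ap

cfg = ap.SpectrumSimConfig(aperiodic_exponent=1.5, peak_center=10.0,
                           peak_amplitude=2.0, peak_width=0.8)
ts = ap.simulate_timeseries(cfg, duration_s=60.0, fs=500.0, seed=1)

segments = ap.segment_recording(ts, segment_len_s=5.0, min_segments=10)
spec = ap.welch_psd(segments, fs=ts.fs)

alpha_frac = ap.relative_alpha_power(spec)
raw_max = spec.freqs[np.argmax(spec.power)]
paf = ap.estimate_paf(spec)

print(f"{len(segments)} segments of {len(segments[0])} samples")
print(f"frequency resolution: {spec.df:.3f} Hz ({spec.freqs.size} bins)")
print(f"raw PSD maximum at {raw_max:.1f} Hz -- the 1/f background "
      "dominates low frequencies")
print(f"PAF after 1/f removal: {paf.center:.2f} Hz (truth 10.0), "
      f"valid={paf.valid}")
print(f"relative alpha power (7-13 Hz over 1-55 Hz): {alpha_frac:.3f}")
# The raw spectrum peaks at its lowest frequencies, which is why the peak
# is located on the 1/f-detrended residual instead.  Relative alpha power
# is the alpha-band fraction of broadband power; the planted 10 Hz
# oscillation lifts it well above the flat-spectrum baseline 31/271 ~ 0.11.
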