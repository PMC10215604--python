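"""Preprocess one synthetic 12-lead record: denoise, segment, normalise.

Generates a single tachycardia-like record, removes baseline wander with the
Daubechies-6 wavelet recipe, cuts 2 s windows and z-scores them. The printed
band powers show the sub-0.7 Hz drift being suppressed while the beat-band
content survives.
"""

import numpy as np

from galslo.preprocess import denoise, preprocess_record
from galslo.synthetic import ClassEffect, SynthConfig, generate_records

cfg = SynthConfig(classes={"T": ClassEffect(bpm=120)}, n_patients_per_class=1,
                  record_seconds=(12.0, 12.0), informative_leads=(2,),
                  baseline_amp=0.4, seed=0)
record = generate_records(cfg)[0]

lead_ii = record.signals[1]
clean = denoise(lead_ii, record.fs)


def band_power(x, lo, hi):
    freqs = np.fft.rfftfreq(len(x), d=1 / record.fs)
    spec = np.abs(np.fft.rfft(x)) ** 2
    return spec[(freqs >= lo) & (freqs <= hi)].sum()


print(f"record {record.record_id}: {record.duration:.1f} s, label {record.label}")
print(f"baseline band (<0.7 Hz) power: {band_power(lead_ii, 0, 0.7):.1f} -> "
      f"{band_power(clean, 0, 0.7):.3f} after denoising")
print(f"beat band (1-40 Hz) power:     {band_power(lead_ii, 1, 40):.1f} -> "
      f"{band_power(clean, 1, 40):.1f} (beat content retained, broadband "
      f"noise in the band shrunk)")

segments = preprocess_record(record, T_L=2)
print(f"2 s segmentation: {len(segments)} windows "
      f"(floor(12/2) = 6, trailing remainder dropped)")
sd = segments[0].lead_signals.std(axis=1)
print(f"after z-score, per-lead sd of the first window: "
      f"min {sd.min():.6f}, max {sd.max():.6f} (unit variance)")
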