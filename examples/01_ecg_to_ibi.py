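"""From a raw ECG trace to a clean 4 Hz inter-beat-interval series.

Synthesizes one minute of noisy 512 Hz ECG with known R-peak times, then runs
the preprocessing chain: zero-phase band-pass (0.6-20 Hz), adaptive R-peak
detection, IBI computation, outlier cleaning, and 4 Hz resampling.
"""

import numpy as np

from cardiosync import (EcgNoiseConfig, bandpass_filter, clean_ibi, compute_ibi,
                        detect_rpeaks, generate_ecg_from_rpeaks, resample_ibi)

rng = np.random.default_rng(1)
rr = np.clip(rng.normal(0.85, 0.05, 70), 0.5, 1.4)       # jittered ~70 bpm rhythm
r_times = np.cumsum(rr) + 0.5

ecg, true_idx = generate_ecg_from_rpeaks(r_times, fs=512.0, noise_cfg=EcgNoiseConfig(seed=1))
filtered = bandpass_filter(ecg)
peaks = detect_rpeaks(filtered)
ibi = clean_ibi(compute_ibi(peaks))
uniform = resample_ibi(ibi, rate_hz=4.0)

true_ibi = np.diff(true_idx) / 512.0 * 1000.0
mae = np.abs(ibi.ibi_ms - true_ibi).mean()

print(f"true beats: {len(true_idx)}, detected: {len(peaks.peak_indices)}")
print(f"IBI mean absolute error vs ground truth: {mae:.3f} ms")
print(f"outliers replaced during cleaning: {ibi.replaced_mask.sum()} of {len(ibi)}")
print(f"4 Hz series: {len(uniform)} samples spanning {len(uniform) / 4:.0f} s, "
      f"mean {uniform.values.mean():.1f} ms")
# A sub-millisecond MAE means peak timing is recovered to within one sample
# at 512 Hz; the 4 Hz series is what the synchrony analysis consumes.
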