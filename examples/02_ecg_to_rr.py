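"""Render a noisy ECG waveform from known beats, then recover the beats.

Runs the full acquisition front-end: 0.5-100 Hz band-pass + 50 Hz notch
(zero-phase), derivative/square/integrate R-detection with adaptive
thresholding, and compares detections against the generator's annotations.
"""

import numpy as np

from hrvscreen import (
    AutonomicParams,
    NoiseConfig,
    detect_r_peaks,
    filter_ecg,
    generate_rr_series,
    render_ecg,
)

params = AutonomicParams(hr_mean=72, a_lf=0.03, a_hf=0.05, jitter_sd=15.0)
rr = generate_rr_series(params, 120.0, seed=1)
noise = NoiseConfig(baseline_amp=0.15, mains_amp=0.10, white_sd=0.05)
ecg = render_ecg(rr, sampling_rate=500.0, noise=noise, seed=1)

detected = detect_r_peaks(filter_ecg(ecg))

offsets = np.abs(detected.beat_times[:, None] - ecg.r_annotations[None, :])
matched = offsets.min(axis=0) <= 0.010
print(f"true beats:      {len(ecg.r_annotations)}")
print(f"detected beats:  {len(detected)}")
print(f"matched <=10 ms: {matched.mean() * 100:.1f}%")
print(f"median |offset|: {np.median(offsets.min(axis=0)) * 1000:.2f} ms")
print(
    "\nWith baseline wander, mains interference and white noise added, the"
    "\nfilter+detector chain should still recover essentially every beat"
    "\nwithin a 10 ms tolerance."
)
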