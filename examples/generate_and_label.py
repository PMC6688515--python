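"""Generate pseudo-EEG with a planted alpha source and post-hoc label it.

Builds a 2-minute, 31-channel recording from the linear forward model
(one 8-12 Hz target source with a burst-like envelope among 1/f background
sources), then runs the full labeling chain through the minimum-norm
inverse and compares the recovered epoch labels with the planted truth.
"""

import numpy as np

from posthoclab import (
    ForwardSpec,
    label_recording,
    make_leadfield,
    mix_to_sensors,
    noise_sd_for_snr,
    simulate_sources,
)

fs = 120.0
src = simulate_sources(n_sources=5, n_samples=int(120 * fs), fs=fs,
                       target_band_hz=(8, 12), seed=31)
lf = make_leadfield(n_channels=31, n_sources=5, smoothness=1.5, seed=32)
sd = noise_sd_for_snr(lf.A, src.S, snr_db=0.0)
rec = mix_to_sensors(src, ForwardSpec(A=lf.A, sensor_noise_sd=sd, seed=33))

ds, manifest = label_recording(
    rec,
    method="mne",
    leadfield=lf.A,
    component_policy=("max_band_power", (8, 12)),
    ptp_threshold_uv=None,
    seed=0,
)

spe = int(fs)
n_w = src.n_samples // spe
truth = (src.true_envelope[: n_w * spe] ** 2).reshape(n_w, spe).mean(axis=1)
r = np.corrcoef(ds.labels.z_epoch, truth)[0, 1]

print(f"epochs labeled:          {ds.n_epochs}")
print(f"selected target source:  {manifest['target_source']} "
      f"(planted source is {src.target_index})")
print(f"corr(labels, planted epoch power): {r:.3f}")
print(f"class balance (binary):  {np.bincount(ds.labels.y_epoch)[1:]}")
print()
print("The correlation near 1 means the post-hoc labels recover the planted")
print("envelope power; the 50/50 class split reflects the median threshold.")
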