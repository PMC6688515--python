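"""Fit the two supervised band-power decoders on planted-ground-truth data.

CSP + rLDA classifies high- vs low-power epochs (AUC); SPoC regresses the
continuous envelope power (Pearson rho) and its spatial pattern is compared
with the planted lead-field column.
"""

import numpy as np

from posthoclab import (
    evaluate_cell,
    fit_spoc,
    make_benchmark_dataset,
    spatial_pattern,
)

ds = make_benchmark_dataset(n_epochs=800, n_channels=20, n_background=10,
                            snr_db=5.0, seed=3)

csp = evaluate_cell(ds, "csp", 800, 0.0, "binary", seed=0)
spoc = evaluate_cell(ds, "spoc", 800, 0.0, "regression", seed=0)

model = fit_spoc(ds.epochs, ds.labels.z_epoch)
pat = spatial_pattern(model.C, model.w)
tp = ds.meta["true_pattern"]
cos = abs(pat @ tp) / np.linalg.norm(pat) / np.linalg.norm(tp)

print(f"CSP  holdout AUC (chronological 5-fold): {csp['mean']:.3f} "
      f"+- {csp['sd']:.3f}")
print(f"SPoC holdout rho (chronological 5-fold): {spoc['mean']:.3f} "
      f"+- {spoc['sd']:.3f}")
print(f"SPoC pattern vs planted pattern cosine:  {cos:.3f}")
print()
print("AUC/rho near 1 show both decoders recover the planted comodulating")
print("source; the cosine near 1 shows the estimated sensor-space pattern")
print("matches the planted mixing column, not just its time course.")
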