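# Methods

## Generative model

Sensor data follow the standard linear forward model

    X = A S + E

with `X` (channels x samples) the recording, `A` (channels x sources) the
lead field whose columns are spatial patterns, `S` the source time courses,
and `E` i.i.d. Gaussian sensor noise with spherical covariance. The
simulator plants a single narrowband target source — a sinusoidal carrier
at the centre of the requested band (8–12 Hz by default), amplitude-
modulated by a smooth positive random envelope — among background sources
with a 1/f power spectrum. The 1/f background is synthesized by shaping
white-noise rFFT amplitudes by f^(-1/2); its log–log periodogram slope is
-1 within the fitting band, the conventional stand-in for task-irrelevant
ongoing activity (the spectral exponent of real background activity varies;
-1 is a modeling choice).

The envelope generator lowpass-filters rectified Gaussian noise at
`1/envelope_timescale_s` (default 2 s, i.e. 0.5 Hz), restores
unit-variance fluctuation after filtering, and offsets the result so its
minimum stays above ~13% of its mean. The lowpass step alone would leave a
nearly constant envelope (relative SD below 10%), because rectified noise
concentrates its power at DC; re-standardizing restores a burst-like
modulation depth (relative SD ~0.3, max/min ~10) comparable to the waxing
and waning of real alpha rhythms, and the positive floor prevents
degenerate zero-power epochs. Filtering is applied to a padded sequence
and trimmed, so forward–backward filter transients never touch the
returned samples.

Scale conventions: background sources have unit variance; the target row's
mean power is `target_power_ratio` (default 1) in the same units; the
planted envelope is returned on the target row's final scale so it is the
exact analytic amplitude. `noise_sd_for_snr` converts a requested
broadband SNR in dB (projected-signal power over per-channel noise power)
into a sensor-noise SD.

Synthetic lead fields are smooth Gaussian random columns (Gaussian kernel
over the channel axis, sigma = 2 channels by default), l2-normalized.
User-supplied lead fields load from delimited text or HDF5 and are used
as-is (no renormalization).

## Inverse mapping

Two routes to a source space:

*Minimum-norm estimate.* The closed form implemented is

    S = A^T (I + lam A A^T)^{-1} X,

computed with a symmetric positive-definite solve. Note that the textbook
ridge minimizer of ||X - A S||^2 + lam ||S||^2 is
`A^T (A A^T + lam I)^{-1} X`; the form above equals 1/lam times the
minimizer of the lam-reparameterized cost. The two differ only by a global
positive factor, which cannot change the order of envelope-derived labels
or any percentile discretization; both are exposed (`MNEConfig.form`),
with the first as default.

The regularization constant is chosen by generalized cross-validation over
a 30-point log-spaced grid in [1e-6, 1e2]:

    GCV(lam) = (||X - H X||_F^2 / N_t) / (trace(I - H)/N_c)^2,
    H = A A^T (I + lam A A^T)^{-1},

the influence matrix consistent with the closed form above. Ties break
toward larger lam (stronger regularization). Because H's eigenvalues are
d/(1 + lam d) for eigenvalues d of A A^T, trace(I - H) can be non-positive
at small lam when the lead field's largest singular value exceeds 1; such
candidates are skipped with a warning. With sub-unit singular values the
score behaves as expected: pure noise drives the selection to the grid
maximum, noiseless in-range data to the grid minimum.

*ICA.* fastICA (log-cosh contrast, deflation, max 500 iterations, tol
1e-6, seeded and hence deterministic) estimates an unmixing matrix Phi;
sources are `S = Phi X` exactly (no re-centering applied to the product,
so the algebraic identity holds; bandpassed input is zero-mean in
practice). Each row is sign-flipped to non-negative skewness — envelope
extraction is sign-invariant, but a fixed convention makes results
reproducible. The default of 20 components is clipped to the channel count
with a warning. The implementation behind the contract is
scikit-learn's FastICA.

*Rescaling.* ICA components have arbitrary scale; each row is
l2-normalized and multiplied by the mean over channels of its inner
product with each channel. In the full pipeline this rescaling is applied
on the ICA route only: minimum-norm amplitudes already carry a physical
scale, and replacing it distorts the relative band power that the
`max_band_power` component-selection policy relies on.

## Label extraction

The chain: (1) optional artifact scan of the raw recording — bandpass
0.7–25 Hz, non-overlapping 1-s windows, reject a window iff any channel's
peak-to-peak amplitude strictly exceeds 80 uV; (2) zero-phase 5th-order
Butterworth bandpass (second-order sections) to the band of interest;
(3) inverse mapping and target-source selection (random, fixed index, or
maximal band power — all seed-deterministic); (4) envelope
`z = |H{s_z}|`; (5) epoching from sample 0, trailing partial window
dropped, rejected windows removed from data and labels alike; (6) epoch
label = window mean of z^2 (average power; window mean of z is available
via `label_mode="amplitude"` for users who prefer the amplitude envelope
itself); (7) optional discretization — binary at the median (class 1
below-or-equal), ternary at the 33rd/66th percentiles (linear
interpolation, boundary ties to the lower class).

Every step is a pure function of the recording and the configuration, so
labeling twice is bit-identical, and the manifest returned by
`label_recording` suffices to regenerate the labels from the raw array
(`relabel_from_manifest`). Hilbert edge effects are not trimmed from the
labels (validation metrics exclude half a second per edge instead).
Scaling the recording by c > 0 scales z by c on the minimum-norm route and
leaves discrete labels unchanged.

Sources within a recording are ranked by the variance of their epoch
labels and tagged into z-variance tertiles (thresholds at the 33rd/66th
percentiles of the variances, ties downward) — the grouping variable for
the label-variability analyses.

## Label-noise models

Regression (continuous labels):

    z_n = z + sqrt((1-(1-xi)^2)/(1-xi)^2) * sqrt(var(z)) * eta,
    eta ~ N(0,1) i.i.d.

so that population corr(z, z_n) = 1 - xi and var(z_n)/var(z) =
1/(1-xi)^2. `var(z)` is the sample variance (ddof = 1) of the supplied
labels; eta is standard normal (the explicit sqrt(var(z)) factor fixes its
scale). xi in [0, 1).

Classification (discrete labels): xi = 2 (1 - P[y_n = y]); each epoch
flips independently with probability xi/2, the replacement drawn uniformly
from the remaining classes. xi in [0, 2) is accepted — xi = 1 makes binary
labels independent of the truth, and values above 1 produce
anti-correlated labels. Flip decisions and replacements come from a single
seeded stream in epoch order.

Both models are i.i.d. across epochs; temporally structured label noise is
out of scope.

## Decoders

*CSP.* Class spatial covariances are per-epoch `X(e) X(e)^T` averaged
within class (no mean-centering — epochs are bandpassed and hence
zero-mean; no trace normalization by default, flag available). The pooled
covariance is `C = C1 + C2` (eigenvectors are invariant to the pooled-vs-
mean convention). The generalized eigenproblem
`W^T (C1 - C2) = Lambda W^T C` is solved by symmetric whitening
(`C^{-1/2}` with an eigenvalue floor of 1e-10 relative for rank control);
the returned `W_full` jointly diagonalizes C1 and C2. Only the two
filters of the extreme eigenvalues are kept. Features are per-epoch
variances of the filtered time courses, log-transformed by default, and
classified by LDA with analytic (Ledoit–Wolf) shrinkage of the pooled
covariance; AUC is computed from the continuous decision scores. If the
pooled covariance is rank-deficient, a small identity shrinkage is applied
with a warning.

*SPoC.* `C` is the mean per-epoch covariance; `C_z` weights each epoch's
covariance by the z-score-standardized label (the centering makes
`w^T C_z w` the covariance of projected power with z; a raw mode without
standardization is available). The filter is the top generalized
eigenvector of `(C_z, C)`, l2-normalized with a sign convention on its
largest component (projected power is invariant to the sign). Predictions
are per-epoch variances of the filtered test epochs; the sensor-space
pattern of a filter is `a = C w / (w^T C w)`.

## Benchmarking

Chronological k-fold (default 5) splits epochs into contiguous temporal
blocks (earliest blocks take the remainder); each block is tested once
with the rest as training. Dataset-size cells take the chronologically
first n epochs. Noise of intensity xi corrupts the *training* labels only;
evaluation is against the clean post-hoc labels, so scores measure what
the decoder recovered of the ground truth rather than the injected noise
(a flag corrupts test labels too, for the alternative convention).
Metrics: AUC (binary, rank statistic with averaged ties), plain accuracy
(ternary; classes are near-balanced by construction), Pearson rho
(regression). Degenerate cells (single-class training fold, zero-variance
predictions) yield NaN with a warning, never silently. Sweep cells are
cached by the SHA-256 of their canonical config JSON, making reruns
resumable, and results are emitted as a long-format table (one row per
cell, fold, and seed).

## Study conditions used by the test and acceptance suites

Problem sizes were chosen as the smallest that make each property sharp:
noise laws at n = 100,000 labels; moment checks of the mixer at n = 10^6
samples; decoder recovery on 20-channel datasets (1 planted + 10
background sources) with 800 epochs for SPoC and 1,000 for CSP at 5 dB
broadband SNR; the noise-degradation study on 100-epoch datasets at
-10 dB over 10 generator seeds — a deliberately small, low-SNR regime
emulating the hard end of real recordings, where maximal supervision
noise (xi = 0.8) leaves decoders at chance level within the simulation's
confidence interval while the degradation remains monotone across
xi in {0, 0.1, 0.2, 0.4, 0.8}.

## What the synthetic data does and does not show

The generator reproduces the features the labeling chain relies on — a
narrowband comodulating source with known envelope, 1/f backgrounds,
linear mixing, stationary sensor noise — so passing tests demonstrate
correctness of the machinery and recoverability under the model's
assumptions. Real recordings additionally contain non-stationary source
dynamics, correlated and non-Gaussian artifacts, moving noise floors, and
head-geometry-structured (not smooth-random) lead fields; performance
numbers measured here do not transfer to real data, and the framework's
stationary inverse mappings (minimum-norm, fastICA) would deliver
time-varying source mixtures under non-stationarity. Artifact modeling,
FEM/BEM head geometry, free source orientations, and adaptive/online
decomposition are out of scope.

## Numerical choices

- All randomness flows through `numpy.random.default_rng(seed)`; one
  generator per operation call, seeds recorded in metadata.
- Butterworth filters are designed as second-order sections and applied
  forward–backward (zero phase). Band edges must lie strictly inside
  (0, fs/2).
- Generalized eigenproblems use symmetric whitening with a relative
  eigenvalue floor of 1e-10.
- Linear solves use `scipy.linalg.solve(..., assume_a="pos")`; the
  closed-form inverse agrees with an explicit dense inverse to ~1e-10
  relative and is asserted to in the tests.
- Percentiles use linear interpolation; all boundary ties resolve to the
  lower class/tertile.
- log-variance features are floored at 1e-300 before the logarithm.
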