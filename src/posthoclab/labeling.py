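"""Post-hoc label extraction and epoch-level preprocessing.

The label pipeline is: bandpass the recording to the frequency band of
interest (8-12 Hz alpha by default), project it to the source space, select
a target source, take the magnitude of the Hilbert transform of that source
as the continuous target variable z, segment data and z into non-overlapping
fixed-length windows, drop windows marked artifactual (peak-to-peak
threshold), and reduce z per epoch to its average power. Discrete class
labels y are percentile memberships of the epoch labels. Every step is a
deterministic function of the data and the configuration, so labels are
exactly recoverable from the raw recording plus metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .synthgen import ContinuousRecording

__all__ = [
    "LabelSet",
    "EpochedDataset",
    "bandpass",
    "extract_envelope",
    "detect_artifacts",
    "epoch_and_label",
    "discretize_labels",
    "variance_tertiles",
]


@dataclass
class LabelSet:
    """Continuous and (optionally) discretized post-hoc labels."""

    z_cont: np.ndarray | None = None  # per-sample envelope, >= 0
    z_epoch: np.ndarray | None = None  # per-epoch label
    y_epoch: np.ndarray | None = None  # integer classes {1,2} or {1,2,3}
    target_source: int | None = None
    band_hz: tuple[float, float] | None = None
    tertile: str | None = None  # "low" | "medium" | "high"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.z_cont is not None:
            self.z_cont = np.asarray(self.z_cont, dtype=float)
            if np.any(self.z_cont < 0):
                raise ValueError("z_cont must be non-negative")
        if self.z_epoch is not None:
            self.z_epoch = np.asarray(self.z_epoch, dtype=float)
        if self.y_epoch is not None:
            self.y_epoch = np.asarray(self.y_epoch, dtype=int)
            if self.z_epoch is not None and len(self.y_epoch) != len(self.z_epoch):
                raise ValueError("y_epoch and z_epoch lengths differ")


@dataclass
class EpochedDataset:
    """Artifact-free fixed-length epochs with aligned labels."""

    epochs: np.ndarray  # (n_epochs, n_channels, samples_per_epoch)
    labels: LabelSet
    rejected_mask: np.ndarray  # bool per original window
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.rejected_mask = np.asarray(self.rejected_mask, dtype=bool)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epoch, channel, sample)")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    def subset(self, idx) -> "EpochedDataset":
        """New dataset holding epochs ``idx`` (labels sliced to match)."""
        idx = np.asarray(idx)
        lab = self.labels
        return EpochedDataset(
            epochs=self.epochs[idx],
            labels=LabelSet(
                z_epoch=None if lab.z_epoch is None else lab.z_epoch[idx],
                y_epoch=None if lab.y_epoch is None else lab.y_epoch[idx],
                target_source=lab.target_source,
                band_hz=lab.band_hz,
                tertile=lab.tertile,
                meta=dict(lab.meta),
            ),
            rejected_mask=self.rejected_mask,
            fs=self.fs,
            meta=dict(self.meta),
        )


def _design_bandpass(low_hz: float, high_hz: float, fs: float, order: int):
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < fs/2"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass(
    rec: ContinuousRecording, low_hz: float, high_hz: float, order: int = 5
) -> ContinuousRecording:
    """Zero-phase Butterworth bandpass (forward-backward, SOS sections)."""
    sos = _design_bandpass(low_hz, high_hz, rec.fs, order)
    Xf = signal.sosfiltfilt(sos, rec.X, axis=1)
    meta = dict(rec.meta)
    meta["band_hz"] = (low_hz, high_hz)
    return ContinuousRecording(X=Xf, fs=rec.fs, channel_names=list(rec.channel_names), meta=meta)


def extract_envelope(s_z: np.ndarray) -> np.ndarray:
    """Band-power envelope: magnitude of the analytic (Hilbert) signal."""
    s_z = np.asarray(s_z, dtype=float)
    if s_z.ndim != 1 or s_z.size < 8:
        raise ValueError("s_z must be a 1-D vector of at least 8 samples")
    if not np.all(np.isfinite(s_z)):
        raise ValueError("s_z contains non-finite values")
    return np.abs(signal.hilbert(s_z))


def detect_artifacts(
    rec: ContinuousRecording,
    ptp_threshold_uv: float = 80.0,
    detect_band: tuple[float, float] | None = (0.7, 25.0),
    window_s: float = 1.0,
) -> np.ndarray:
    """Flag windows whose peak-to-peak amplitude exceeds a threshold.

    The recording is bandpassed to ``detect_band`` (5th-order Butterworth;
    pass None to skip filtering), cut into the same non-overlapping windows
    as epoching, and a window is rejected iff any channel's (max - min)
    strictly exceeds ``ptp_threshold_uv``. Returns a boolean mask, True =
    rejected, of length floor(n_samples / (fs * window_s)).
    """
    if ptp_threshold_uv <= 0:
        raise ValueError("ptp_threshold_uv must be > 0")
    X = rec.X
    if detect_band is not None:
        sos = _design_bandpass(detect_band[0], detect_band[1], rec.fs, 5)
        X = signal.sosfiltfilt(sos, X, axis=1)
    spe = int(round(rec.fs * window_s))
    n_windows = X.shape[1] // spe
    mask = np.zeros(n_windows, dtype=bool)
    for w in range(n_windows):
        seg = X[:, w * spe : (w + 1) * spe]
        ptp = seg.max(axis=1) - seg.min(axis=1)
        mask[w] = bool(np.any(ptp > ptp_threshold_uv))
    return mask


def epoch_and_label(
    X_band: ContinuousRecording,
    z_cont: np.ndarray,
    window_s: float = 1.0,
    rejected_mask: np.ndarray | None = None,
    label_mode: str = "power",
) -> EpochedDataset:
    """Segment data and envelope into non-overlapping windows and label them.

    Windows start at sample 0; a trailing partial window is dropped;
    rejected windows are removed from both data and labels. The epoch label
    is the window mean of z^2 (``label_mode="power"``, default) or of z
    (``label_mode="amplitude"``).
    """
    if label_mode not in ("power", "amplitude"):
        raise ValueError("label_mode must be 'power' or 'amplitude'")
    z_cont = np.asarray(z_cont, dtype=float)
    if X_band.n_samples != z_cont.size:
        raise ValueError("X_band and z_cont must be aligned in samples")
    spe = int(round(X_band.fs * window_s))
    n_windows = X_band.n_samples // spe
    if rejected_mask is None:
        rejected_mask = np.zeros(n_windows, dtype=bool)
    rejected_mask = np.asarray(rejected_mask, dtype=bool)
    if rejected_mask.size != n_windows:
        raise ValueError(
            f"rejected_mask has {rejected_mask.size} entries, expected {n_windows}"
        )
    keep = np.flatnonzero(~rejected_mask)
    if keep.size == 0:
        raise ValueError("zero usable epochs after artifact rejection")
    epochs = np.stack(
        [X_band.X[:, w * spe : (w + 1) * spe] for w in keep], axis=0
    )
    zw = z_cont[: n_windows * spe].reshape(n_windows, spe)
    if label_mode == "power":
        z_epoch = np.mean(zw**2, axis=1)[keep]
    else:
        z_epoch = np.mean(zw, axis=1)[keep]
    labels = LabelSet(
        z_epoch=z_epoch,
        band_hz=X_band.meta.get("band_hz"),
        meta={"window_s": window_s, "label_mode": label_mode},
    )
    return EpochedDataset(
        epochs=epochs,
        labels=labels,
        rejected_mask=rejected_mask,
        fs=X_band.fs,
        meta={"window_s": window_s, "kept_windows": keep.tolist()},
    )


def discretize_labels(z_epoch: np.ndarray, scheme: str = "binary") -> np.ndarray:
    """Percentile class labels from continuous epoch labels.

    binary: class 1 iff z <= median, else 2 (top/bottom 50th percentile).
    ternary: thresholds at the 33rd and 66th percentiles (linear
    interpolation); ties at a boundary go to the lower class.
    """
    z = np.asarray(z_epoch, dtype=float)
    if scheme not in ("binary", "ternary"):
        raise ValueError("scheme must be 'binary' or 'ternary'")
    n_classes = 2 if scheme == "binary" else 3
    if z.size < n_classes:
        raise ValueError(f"need at least {n_classes} epochs for {scheme} labels")
    if np.ptp(z) == 0:
        raise ValueError("all epoch labels equal; no contrast to discretize")
    if scheme == "binary":
        thresholds = [np.percentile(z, 50)]
    else:
        thresholds = [np.percentile(z, 33), np.percentile(z, 66)]
    y = np.ones(z.size, dtype=int)
    for thr in thresholds:
        y += (z > thr).astype(int)
    return y


def variance_tertiles(label_sets: list[LabelSet]) -> list[LabelSet]:
    """Tag each source's label set by its z-variance tertile.

    Variances of z_epoch are computed per source; sources are partitioned
    at the 33rd/66th percentiles of those variances into low / medium /
    high, ties at a boundary to the lower tertile. With fewer than 3
    sources the tags stay unset (warning).
    """
    if len(label_sets) < 3:
        warnings.warn("fewer than 3 sources; tertiles left unset", stacklevel=2)
        return label_sets
    variances = np.array([np.var(ls.z_epoch) for ls in label_sets])
    lo, hi = np.percentile(variances, 33), np.percentile(variances, 66)
    names = ("low", "medium", "high")
    for ls, v in zip(label_sets, variances):
        ls.tertile = names[int(v > lo) + int(v > hi)]
    return label_sets
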