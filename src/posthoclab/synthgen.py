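"""Pseudo-M/EEG generation with known ground truth.

Sensor data follow the linear forward model ``X = A S + E``: a source matrix
``S`` (one narrowband oscillatory target source with a smooth amplitude
envelope, embedded among 1/f background sources) is projected through a
mixing/lead-field matrix ``A`` onto the channels, and i.i.d. Gaussian sensor
noise ``E`` is added. Because the target envelope is planted, every label a
downstream pipeline derives can be checked against ground truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SourceActivity",
    "ContinuousRecording",
    "ForwardSpec",
    "simulate_sources",
    "mix_to_sensors",
    "make_leadfield",
    "load_leadfield",
    "noise_sd_for_snr",
]


@dataclass
class SourceActivity:
    """Ground-truth source time courses.

    Attributes
    ----------
    S : ndarray, shape (n_sources, n_samples)
        Source time courses (arbitrary units).
    fs : float
        Sampling rate in Hz.
    target_index : int
        Row of ``S`` holding the planted narrowband target source.
    true_envelope : ndarray, shape (n_samples,)
        The planted (noise-free) amplitude envelope of the target source.
    meta : dict
        Generation parameters, including the seed.
    """

    S: np.ndarray
    fs: float
    target_index: int
    true_envelope: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.true_envelope = np.asarray(self.true_envelope, dtype=float)
        if not np.all(np.isfinite(self.S)):
            raise ValueError("source matrix contains non-finite values")
        if not (0 <= self.target_index < self.S.shape[0]):
            raise ValueError("target_index out of range")
        if np.any(self.true_envelope < 0):
            raise ValueError("true_envelope must be non-negative")

    @property
    def n_sources(self) -> int:
        return self.S.shape[0]

    @property
    def n_samples(self) -> int:
        return self.S.shape[1]


@dataclass
class ContinuousRecording:
    """Multichannel continuous recording (channels x samples, in microvolt)."""

    X: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (channels x samples)")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.X.shape[0])]
        if len(self.channel_names) != self.X.shape[0]:
            raise ValueError("channel_names length must equal number of channels")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class ForwardSpec:
    """Forward (mixing) model: lead field, sensor-noise level, seed.

    ``A`` maps sources to channels; its columns are the spatial patterns.
    Sensor noise is i.i.d. Gaussian with standard deviation
    ``sensor_noise_sd`` on every channel (spherical noise covariance).
    """

    A: np.ndarray
    sensor_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be >= 0")
        col_norms = np.linalg.norm(self.A, axis=0)
        if np.any(col_norms == 0):
            raise ValueError("lead field has an all-zero column")

    @property
    def n_channels(self) -> int:
        return self.A.shape[0]

    @property
    def n_sources(self) -> int:
        return self.A.shape[1]


def _pink_noise(n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-power noise: white-noise rFFT amplitudes shaped by f^(-1/2)."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** -0.5
    x = np.fft.irfft(spec * scale, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _smooth_envelope(
    n_samples: int, fs: float, timescale_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Rectified Gaussian noise, lowpassed at 1/timescale, offset positive.

    The offset keeps min(env) at ~13% of mean(env) so no epoch has
    vanishing target power.
    """
    cutoff = 1.0 / timescale_s
    if cutoff >= fs / 2:
        raise ValueError("envelope_timescale_s too short for the sampling rate")
    pad = int(5 * timescale_s * fs)  # absorb filtfilt edge transients
    raw = np.abs(rng.standard_normal(n_samples + 2 * pad))
    sos = signal.butter(2, cutoff, btype="low", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, raw)[pad : pad + n_samples]
    sd = env.std()
    if sd <= 0:  # pathological flat draw; fall back to a constant envelope
        return np.ones(n_samples)
    # restore unit-variance fluctuation (the lowpass removes most of the
    # rectified noise's power), giving burst-like modulation depth instead
    # of a near-constant envelope
    env = (env - env.mean()) / sd
    env = env - env.min()
    env = env + 0.15 * env.mean()
    return env / env.mean()


def simulate_sources(
    n_sources: int,
    n_samples: int,
    fs: float,
    target_band_hz: tuple[float, float] = (8.0, 12.0),
    envelope_timescale_s: float | None = 2.0,
    seed: int = 0,
    target_power_ratio: float = 1.0,
) -> SourceActivity:
    """Simulate one narrowband target source among 1/f background sources.

    The target row is a sinusoidal carrier at the centre of
    ``target_band_hz``, amplitude-modulated by a smooth positive random
    envelope (lowpass-filtered rectified Gaussian noise with cutoff
    ``1/envelope_timescale_s``). Passing ``envelope_timescale_s=None``
    forces a constant (unit) envelope. All other rows are 1/f-spectrum
    noise with unit variance. The target row is scaled so that its mean
    power is ``target_power_ratio`` times a background source's power.

    The target row is placed at index 0; ``target_index`` records it.
    Identical ``seed`` gives bit-identical output.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    if n_samples < fs:
        raise ValueError("need at least one second of samples")
    low, high = target_band_hz
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"target_band_hz={target_band_hz} must lie inside (0, fs/2)={fs / 2}"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    carrier_hz = 0.5 * (low + high)
    phase = rng.uniform(0, 2 * np.pi)
    if envelope_timescale_s is None or not np.isfinite(envelope_timescale_s):
        envelope = np.ones(n_samples)
    else:
        envelope = _smooth_envelope(n_samples, fs, envelope_timescale_s, rng)
    carrier = np.sin(2 * np.pi * carrier_hz * t + phase)
    target = envelope * carrier
    # scale to requested mean power relative to unit-variance backgrounds
    p = np.mean(target**2)
    gain = np.sqrt(target_power_ratio / p) if p > 0 else 1.0
    target = gain * target
    envelope = gain * envelope

    S = np.empty((n_sources, n_samples))
    S[0] = target
    for i in range(1, n_sources):
        S[i] = _pink_noise(n_samples, rng)
    return SourceActivity(
        S=S,
        fs=fs,
        target_index=0,
        true_envelope=envelope,
        meta={
            "seed": seed,
            "carrier_hz": carrier_hz,
            "target_band_hz": tuple(target_band_hz),
            "envelope_timescale_s": envelope_timescale_s,
            "target_power_ratio": target_power_ratio,
        },
    )


def mix_to_sensors(sources: SourceActivity, spec: ForwardSpec) -> ContinuousRecording:
    """Project sources to channels: ``X = A S + E``, E ~ N(0, sd^2) i.i.d."""
    if spec.n_sources != sources.n_sources:
        raise ValueError(
            f"lead field has {spec.n_sources} columns but sources has "
            f"{sources.n_sources} rows"
        )
    rng = np.random.default_rng(spec.seed)
    X = spec.A @ sources.S
    if spec.sensor_noise_sd > 0:
        X = X + spec.sensor_noise_sd * rng.standard_normal(X.shape)
    return ContinuousRecording(
        X=X,
        fs=sources.fs,
        meta={
            "seed": spec.seed,
            "sensor_noise_sd": spec.sensor_noise_sd,
            "target_index": sources.target_index,
        },
    )


def make_leadfield(
    n_channels: int, n_sources: int, smoothness: float = 2.0, seed: int = 0
) -> ForwardSpec:
    """Random spatially smooth lead field with unit-norm columns.

    Each column is Gaussian noise over the channel axis smoothed with a
    Gaussian kernel (sigma = ``smoothness`` channels), then l2-normalized —
    a stand-in for an anatomical head model when none is supplied.
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n_channels, n_sources))
    if smoothness > 0:
        A = gaussian_filter1d(A, sigma=smoothness, axis=0, mode="nearest")
    norms = np.linalg.norm(A, axis=0)
    # a smoothed column can in principle collapse; redraw those from white noise
    dead = norms < 1e-12
    if np.any(dead):
        A[:, dead] = rng.standard_normal((n_channels, int(dead.sum())))
        norms = np.linalg.norm(A, axis=0)
    A = A / norms
    return ForwardSpec(A=A, seed=seed)


def load_leadfield(path: str | os.PathLike) -> ForwardSpec:
    """Load a lead field from delimited text or HDF5 (dataset "leadfield").

    Values are taken as-is; columns are NOT renormalized.
    """
    path = os.fspath(path)
    if h5py.is_hdf5(path):
        with h5py.File(path, "r") as f:
            if "leadfield" not in f:
                raise ValueError(f"{path}: HDF5 file has no 'leadfield' dataset")
            A = np.asarray(f["leadfield"], dtype=float)
    else:
        with open(path) as f:
            text = f.read()
        if not text.strip():
            raise ValueError(f"{path}: empty lead-field file")
        delimiter = "," if "," in text else None
        rows = []
        width = None
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter else line.split()
            try:
                row = [float(p) for p in parts if p != ""]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric entry") from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ValueError(f"{path}:{lineno}: ragged row ({len(row)} != {width})")
            rows.append(row)
        if not rows:
            raise ValueError(f"{path}: no numeric rows found")
        A = np.asarray(rows, dtype=float)
    if A.ndim != 2:
        raise ValueError(f"{path}: lead field must be a 2-D matrix, got shape {A.shape}")
    return ForwardSpec(A=A)


def noise_sd_for_snr(A: np.ndarray, S: np.ndarray, snr_db: float) -> float:
    """Sensor-noise sd giving a requested broadband SNR in dB.

    SNR is the ratio of mean channel power of the projected signal ``A S``
    to the noise power per channel: sd = sqrt(P_signal / 10^(snr/10)).
    """
    proj = np.asarray(A) @ np.asarray(S)
    p_signal = float(np.mean(proj**2))
    return float(np.sqrt(p_signal / 10 ** (snr_db / 10.0)))
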