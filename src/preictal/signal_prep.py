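"""EEG preprocessing: resampling, band-pass filtering, epoching, STFT features.

The featurization target is a per-epoch time-frequency matrix: 30 s epochs,
short-time Fourier transform with a 1 s Hamming window and 50% overlap and no
epoch padding, which yields exactly 59 frames at every supported rate and a
1 Hz one-sided frequency grid.  At 128 Hz the full one-sided spectrum is kept
(65 bins, 0-64 Hz); at 256/512 Hz bins up to 90 Hz are kept minus the
55-64 Hz power-line band (81 bins).

Magnitudes are log-scaled as ``log(1 + |S|)``; per-channel standardization
with training-split statistics lives in :mod:`preictal.datasets` so that test
data never leak into the normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import NamedTuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy.fft import rfft

from .annotations import ConfigurationError, PeriodLabeling

__all__ = [
    "Recording",
    "PrepConfig",
    "TFTensor",
    "Epochs",
    "SUPPORTED_FS_OUT",
    "EPOCH_LEN_S",
    "band_for",
    "resample",
    "bandpass",
    "preictal_step",
    "PreictalStep",
    "segment_epochs",
    "stft_features",
    "freq_mask",
    "preprocess",
]

SUPPORTED_FS_OUT = (128, 256, 512)
EPOCH_LEN_S = 30.0
LINE_NOISE_BAND_HZ = (55, 64)  # inclusive, masked at fs_out >= 256


@dataclass
class Recording:
    """Multichannel EEG: ``signal`` is (channels, samples) in microvolts."""

    signal: np.ndarray
    fs: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels, samples)")
        if self.signal.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.signal.shape[0]} signal rows vs {len(self.channel_names)} channel names"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def band_for(fs_out: int) -> tuple[float, float]:
    """Band-pass edges (Hz) tied to the output rate: (0.5, 50) at 128 Hz,
    (0.5, 90) at 256/512 Hz."""
    if fs_out == 128:
        return (0.5, 50.0)
    if fs_out in (256, 512):
        return (0.5, 90.0)
    raise ConfigurationError(f"unsupported output rate {fs_out}; supported: {SUPPORTED_FS_OUT}")


@dataclass
class PrepConfig:
    """Preprocessing configuration for one featurization run."""

    fs_out: int = 256
    epoch_len_s: float = EPOCH_LEN_S
    stft_window_s: float = 1.0
    stft_overlap: float = 0.5
    band: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fs_out not in SUPPORTED_FS_OUT:
            raise ConfigurationError(f"unsupported fs_out {self.fs_out}")
        if self.band is None:
            self.band = band_for(self.fs_out)
        elif self.band != band_for(self.fs_out):
            raise ConfigurationError(
                f"band {self.band} inconsistent with fs_out {self.fs_out}"
            )

    def to_attrs(self) -> dict:
        return {
            "fs_out": self.fs_out,
            "band_low_hz": self.band[0],
            "band_high_hz": self.band[1],
            "epoch_len_s": self.epoch_len_s,
            "stft_window_s": self.stft_window_s,
            "stft_overlap": self.stft_overlap,
        }


@dataclass
class TFTensor:
    """One epoch's time-frequency matrix (channels × T × F) with its label."""

    values: np.ndarray
    label: int
    epoch_start_s: float
    freq_bins: np.ndarray


class Epochs(NamedTuple):
    """A batch of raw 30 s epochs: data (n, channels, samples) + start times."""

    data: np.ndarray
    start_s: np.ndarray


def resample(recording: Recording, fs_out: int) -> Recording:
    """Polyphase anti-aliased resampling from the native rate to ``fs_out``.

    Decimates directly (not chained through intermediate rates).  Upsampling
    is refused: the native clinical rate is always above the target.
    """
    if fs_out not in SUPPORTED_FS_OUT:
        raise ConfigurationError(f"unsupported fs_out {fs_out}")
    if fs_out > recording.fs:
        raise ValueError(f"cannot upsample {recording.fs} Hz to {fs_out} Hz")
    if fs_out == recording.fs:
        return Recording(recording.signal.copy(), float(fs_out), list(recording.channel_names))
    frac = Fraction(fs_out, int(round(recording.fs)))
    out = sps.resample_poly(recording.signal, frac.numerator, frac.denominator, axis=1)
    return Recording(out.astype(recording.signal.dtype, copy=False), float(fs_out),
                     list(recording.channel_names))


def bandpass(recording: Recording, low: float, high: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    nyq = recording.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"invalid band ({low}, {high}) for fs {recording.fs}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=recording.fs, output="sos")
    out = sps.sosfiltfilt(sos, recording.signal, axis=1)
    return Recording(out.astype(recording.signal.dtype, copy=False), recording.fs,
                     list(recording.channel_names))


def preprocess(recording: Recording, config: PrepConfig) -> Recording:
    """Resample to ``config.fs_out`` then band-pass with the rate's band."""
    rec = resample(recording, config.fs_out)
    return bandpass(rec, *config.band)


class PreictalStep(NamedTuple):
    step_s: float
    total_epochs: int
    achieved_target: bool


def _epochs_per_lead(L_s: float, step_s: float, epoch_len_s: float) -> int:
    return int(np.floor((L_s - epoch_len_s) / step_s)) + 1


def preictal_step(
    L_min: float,
    target_epochs: int,
    epoch_len_s: float = EPOCH_LEN_S,
    *,
    n_leads: int = 1,
    step_floor_s: float = 1.0,
    step_resolution_s: float = 0.5,
) -> PreictalStep:
    """Choose the epoch step (overlap) inside preictal windows.

    Preictal windows are short, so their 30 s epochs overlap just enough that
    the total preictal epoch count over ``n_leads`` windows of L minutes
    reaches ``target_epochs`` (the interictal count) as closely as possible
    from above.  The step is searched on a grid from ``step_floor_s`` to the
    epoch length; if even the floor step cannot reach the target, the floor is
    returned with ``achieved_target=False``.
    """
    L_s = L_min * 60.0
    if L_s < epoch_len_s:
        raise ConfigurationError(f"preictal window {L_s} s shorter than one epoch")
    if target_epochs < 1 or n_leads < 1:
        raise ValueError("target_epochs and n_leads must be >= 1")
    steps = np.arange(step_floor_s, epoch_len_s + 1e-9, step_resolution_s)
    best: PreictalStep | None = None
    # prefer the largest step (least overlap) whose total still meets the target
    for step in steps[::-1]:
        total = n_leads * _epochs_per_lead(L_s, step, epoch_len_s)
        if total >= target_epochs and (best is None or total < best.total_epochs):
            best = PreictalStep(float(step), total, True)
    if best is not None:
        return best
    total = n_leads * _epochs_per_lead(L_s, steps[0], epoch_len_s)
    return PreictalStep(float(steps[0]), total, False)


def segment_epochs(
    recording: Recording,
    labeling: PeriodLabeling,
    label: str,
    step_s: float,
    epoch_len_s: float = EPOCH_LEN_S,
    *,
    skip_flagged_preictal: bool = True,
) -> Epochs:
    """Cut fixed-length epochs from every interval carrying ``label``.

    Epochs start at ``interval_start + k*step_s`` and never cross interval
    boundaries; intervals shorter than one epoch contribute nothing.  Preictal
    intervals of flagged (truncated) lead seizures are skipped by default.
    """
    fs = recording.fs
    n_ep_samples = int(round(epoch_len_s * fs))
    chunks: list[np.ndarray] = []
    starts: list[float] = []
    flagged = set(labeling.flagged_leads)
    for s, e in labeling.with_label(label):
        if label == "preictal" and skip_flagged_preictal and any(
            abs(e - lead) < 1e-6 for lead in flagged
        ):
            continue
        t = s
        while t + epoch_len_s <= e + 1e-9:
            i0 = int(round(t * fs))
            if i0 + n_ep_samples > recording.n_samples:
                break
            chunks.append(recording.signal[:, i0 : i0 + n_ep_samples])
            starts.append(t)
            t += step_s
    if not chunks:
        return Epochs(
            np.empty((0, recording.n_channels, n_ep_samples), dtype=recording.signal.dtype),
            np.empty(0),
        )
    return Epochs(np.stack(chunks), np.asarray(starts))


def freq_mask(fs_out: int) -> np.ndarray:
    """Retained STFT frequency bins in Hz (1 Hz spacing from the 1 s window).

    128 Hz keeps the full one-sided spectrum 0-64 Hz (65 bins); 256/512 Hz
    keep 0-90 Hz minus the 55-64 Hz line-noise band (81 bins) — identical Hz
    lists at 256 and 512.
    """
    if fs_out == 128:
        return np.arange(0, 65)
    if fs_out in (256, 512):
        keep = np.arange(0, 91)
        lo, hi = LINE_NOISE_BAND_HZ
        return keep[(keep < lo) | (keep > hi)]
    raise ConfigurationError(f"unsupported fs_out {fs_out}")


def stft_features(epoch: np.ndarray, fs_out: int, epoch_len_s: float = EPOCH_LEN_S) -> np.ndarray:
    """Log-magnitude STFT of one epoch: (channels, 59, F).

    1 s Hamming window, 50% overlap, no padding: 59 frames for a 30 s epoch.
    The per-channel epoch mean is removed first (keeps DC leakage out of bin
    0); magnitudes are compressed as ``log1p``.
    """
    epoch = np.atleast_2d(np.asarray(epoch))
    fs = int(fs_out)
    n_expected = int(round(epoch_len_s * fs))
    if epoch.shape[-1] != n_expected:
        raise ValueError(f"epoch has {epoch.shape[-1]} samples, expected {n_expected}")
    win = fs  # 1 s window -> 1 Hz bins
    hop = fs // 2
    x = epoch - epoch.mean(axis=-1, keepdims=True)
    frames = sliding_window_view(x, win, axis=-1)[..., ::hop, :]  # (ch, 59, win)
    window = np.hamming(win).astype(x.dtype)
    spec = rfft(frames * window, axis=-1)
    mag = np.abs(spec)[..., freq_mask(fs)]
    return np.log1p(mag)


def featurize_epochs(epochs: Epochs, fs_out: int) -> np.ndarray:
    """Vectorized :func:`stft_features` over a batch: (n, channels, 59, F)."""
    if epochs.data.shape[0] == 0:
        F = freq_mask(fs_out).size
        return np.empty((0, epochs.data.shape[1], 59, F), dtype=np.float32)
    return stft_features(epochs.data, fs_out).astype(np.float32)
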