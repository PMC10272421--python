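"""Preprocessing of raw multi-channel EEG into standardized, band-decomposed epochs.

The pipeline is the standard offline motor-imagery front end: NaN repair,
a 5th-order 1–38 Hz Butterworth bandpass, per-channel z-scoring with
statistics taken from the training split only, 4-s epochs cut from the cue
onset, and a 10-band filter bank (1–4 … 35–38 Hz) feeding the spatial-filter
stage.

Filters are applied zero-phase (forward-backward, ``sosfiltfilt``) by
default; a causal single pass is available via ``zero_phase=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal

#: The 10 sub-bands of the filter bank (Hz).
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (1, 4), (4, 8), (8, 12), (12, 16), (16, 20),
    (20, 24), (24, 28), (28, 32), (32, 35), (35, 38),
)


@dataclass
class RawRecording:
    """Continuous EEG: channels x samples, with cue events for epoching."""

    data: np.ndarray                      # (channels, samples), microvolts
    fs: float
    channel_names: Sequence[str] | None = None
    cue_onsets: np.ndarray | None = None  # sample indices
    labels: np.ndarray | None = None      # per-cue class in {1..4}

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.cue_onsets is not None:
            self.cue_onsets = np.asarray(self.cue_onsets, dtype=int)
            if np.any(np.diff(self.cue_onsets) <= 0):
                raise ValueError("cue_onsets must be strictly increasing")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)


@dataclass
class NormalizationStats:
    """Per-channel mean/std computed on the training split only."""

    mu: np.ndarray
    sigma: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive elementwise")


@dataclass
class EpochSet:
    """Labeled trials: trials x channels x samples."""

    data: np.ndarray
    labels: np.ndarray
    fs: float
    subject_id: str = ""
    session_id: str = ""
    channel_names: Sequence[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("trial count must equal label count")

    @property
    def n_trials(self):
        return self.data.shape[0]

    @property
    def n_channels(self):
        return self.data.shape[1]

    @property
    def n_samples(self):
        return self.data.shape[2]


@dataclass
class FilterBankSpec:
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    order: int = 5
    design: str = "butter"

    def __post_init__(self):
        self.bands = tuple((float(lo), float(hi)) for lo, hi in self.bands)
        if not self.bands:
            raise ValueError("bands must be non-empty")
        for lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band ({lo}, {hi}) has low >= high")

    @property
    def n_bands(self):
        return len(self.bands)


@dataclass
class BandEpochs:
    """Filter-bank output: bands x trials x channels x samples."""

    data: np.ndarray
    spec: FilterBankSpec
    labels: np.ndarray
    fs: float = 250.0
    channel_names: Sequence[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.shape[0] != self.spec.n_bands:
            raise ValueError("first axis must match the number of bands")

    @property
    def n_bands(self):
        return self.data.shape[0]

    @property
    def n_trials(self):
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# operations


def clean_nans(raw: RawRecording) -> RawRecording:
    """Replace NaNs with the mean of the channel's remaining samples.

    A channel with no finite samples cannot be repaired and raises.
    """
    data = raw.data
    if not np.isnan(data).any():
        return raw
    out = data.copy()
    for ch in range(out.shape[0]):
        mask = np.isnan(out[ch])
        if mask.all():
            name = raw.channel_names[ch] if raw.channel_names is not None else str(ch)
            raise ValueError(f"channel {name!r} is entirely NaN and cannot be repaired")
        if mask.any():
            out[ch, mask] = out[ch, ~mask].mean()
    return replace(raw, data=out)


def _butter_sos(low, high, fs, order):
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(raw: RawRecording, low: float = 1.0, high: float = 38.0, order: int = 5,
             zero_phase: bool = True) -> RawRecording:
    """Butterworth bandpass along time; metadata preserved."""
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= raw.fs / 2:
        raise ValueError(f"high cutoff {high} Hz is at or above Nyquist ({raw.fs / 2} Hz)")
    sos = _butter_sos(low, high, raw.fs, order)
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, raw.data, axis=-1)
    else:
        filtered = signal.sosfilt(sos, raw.data, axis=-1)
    return replace(raw, data=filtered)


def normalization_stats(data: np.ndarray, source: str = "train",
                        ddof: int = 0) -> NormalizationStats:
    """Per-channel stats pooled over all training trials and time points.

    ``data`` is (channels, samples) or (trials, channels, samples).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        mu = data.mean(axis=-1)
        sigma = data.std(axis=-1, ddof=ddof)
    elif data.ndim == 3:
        mu = data.mean(axis=(0, 2))
        sigma = data.std(axis=(0, 2), ddof=ddof)
    else:
        raise ValueError("expected 2-D or 3-D data")
    return NormalizationStats(mu=mu, sigma=sigma, source=source)


def zscore(data: np.ndarray, stats: NormalizationStats, divisor: str = "std") -> np.ndarray:
    """Standardize per channel: (X - mu) / sigma.

    ``divisor='var'`` divides by sigma**2 instead; z-score semantics
    (``'std'``) is the default.
    """
    if divisor not in ("std", "var"):
        raise ValueError("divisor must be 'std' or 'var'")
    data = np.asarray(data, dtype=float)
    denom = stats.sigma if divisor == "std" else stats.sigma ** 2
    if data.ndim == 2:      # channels x samples
        return (data - stats.mu[:, None]) / denom[:, None]
    if data.ndim == 3:      # trials x channels x samples
        return (data - stats.mu[None, :, None]) / denom[None, :, None]
    raise ValueError("expected 2-D or 3-D data")


def epoch(raw: RawRecording, window_seconds: float = 4.0) -> EpochSet:
    """Cut one window per cue starting at the cue onset."""
    if raw.cue_onsets is None:
        raise ValueError("recording has no cue onsets")
    n_samples = int(round(window_seconds * raw.fs))
    onsets = raw.cue_onsets
    if onsets.size == 0:
        return EpochSet(
            data=np.empty((0, raw.data.shape[0], n_samples)),
            labels=np.empty(0, dtype=int), fs=raw.fs,
            channel_names=raw.channel_names)
    bad = np.nonzero(onsets + n_samples > raw.data.shape[1])[0]
    if bad.size:
        raise ValueError(
            f"trials {bad.tolist()} extend past the end of the recording "
            f"(window of {n_samples} samples)")
    trials = np.stack([raw.data[:, o:o + n_samples] for o in onsets])
    labels = raw.labels if raw.labels is not None else np.zeros(len(onsets), dtype=int)
    return EpochSet(data=trials, labels=np.asarray(labels), fs=raw.fs,
                    channel_names=raw.channel_names)


def filter_bank(epochs: EpochSet, spec: FilterBankSpec | None = None,
                zero_phase: bool = True) -> BandEpochs:
    """One band-filtered copy of every trial per sub-band."""
    spec = spec or FilterBankSpec()
    nyq = epochs.fs / 2
    out = np.empty((spec.n_bands,) + epochs.data.shape)
    for b, (lo, hi) in enumerate(spec.bands):
        if hi >= nyq:
            raise ValueError(f"band ({lo}, {hi}) Hz is at or above Nyquist ({nyq} Hz)")
        sos = _butter_sos(lo, hi, epochs.fs, spec.order)
        if zero_phase:
            out[b] = signal.sosfiltfilt(sos, epochs.data, axis=-1)
        else:
            out[b] = signal.sosfilt(sos, epochs.data, axis=-1)
    return BandEpochs(data=out, spec=spec, labels=epochs.labels, fs=epochs.fs,
                      channel_names=epochs.channel_names)


def preprocess_recording(raw: RawRecording, low=1.0, high=38.0, order=5,
                         window_seconds=4.0, stats: NormalizationStats | None = None,
                         divisor: str = "std", zero_phase: bool = True) -> EpochSet:
    """Full continuous-data path: clean -> bandpass -> z-score -> epoch.

    When ``stats`` is None they are computed from this recording (use only
    for training data; pass training stats for held-out data).
    """
    raw = clean_nans(raw)
    raw = bandpass(raw, low=low, high=high, order=order, zero_phase=zero_phase)
    if stats is None:
        stats = normalization_stats(raw.data)
    raw = replace(raw, data=zscore(raw.data, stats, divisor=divisor))
    return epoch(raw, window_seconds=window_seconds)
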