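"""Seeded synthetic motor-imagery EEG.

Each trial is ``sum_k a_k s_k(t) + pink + white noise``: the class-specific
source ``s(t)`` is narrowband noise confined to the class's rhythm band,
projected onto a unit spatial pattern concentrated over a small sensor
neighborhood (mimicking the C3/Cz/C4-style topography of event-related
band-power changes).  Per-subject variability is a random perturbation of
the patterns plus a global gain, which creates the cross-subject gap that
subject-independent pipelines must bridge.  Everything is a pure function of
the config, including its seed.

The default four classes use rhythms at 8-12 Hz and 16-24 Hz over four
distinct neighborhoods, so the 10-band filter bank and the LASSO stage have
genuinely informative bands to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocess import EpochSet


def _default_bands():
    return {1: (8.0, 12.0), 2: (8.0, 12.0), 3: (16.0, 24.0), 4: (16.0, 24.0)}


@dataclass
class SynthConfig:
    n_subjects: int = 2
    n_sessions: int = 1
    trials_per_class: int = 20
    C: int = 22
    fs: float = 250.0
    T_seconds: float = 4.0
    class_bands: dict = field(default_factory=_default_bands)
    class_patterns: dict | None = None      # class -> unit vector over channels
    snr: float = 1.0                        # source RMS / background RMS
    subject_shift_sd: float = 0.2
    pink_exponent: float = 1.0              # background power ~ 1/f^exponent
    white_fraction: float = 0.3             # share of background that is white
    seed: int = 0

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        nyq = self.fs / 2
        for c, (lo, hi) in self.class_bands.items():
            if hi >= nyq:
                raise ValueError(f"class {c} band ({lo},{hi}) at or above Nyquist")
        if self.class_patterns is None:
            self.class_patterns = default_patterns(sorted(self.class_bands), self.C)
        for c, p in self.class_patterns.items():
            p = np.asarray(p, dtype=float)
            self.class_patterns[c] = p / np.linalg.norm(p)

    @property
    def n_samples(self):
        return int(round(self.T_seconds * self.fs))


def default_patterns(classes, n_channels):
    """Unit patterns over ``len(classes)`` disjoint sensor neighborhoods."""
    patterns = {}
    width = max(2, n_channels // len(classes))
    for i, c in enumerate(classes):
        p = np.zeros(n_channels)
        start = (i * width) % n_channels
        idx = np.arange(start, start + width) % n_channels
        # smooth bump over the neighborhood
        p[idx] = np.hanning(width + 2)[1:-1]
        patterns[c] = p / np.linalg.norm(p)
    return patterns


def _pink_noise(rng, shape, fs, exponent):
    """Noise with power spectral density ~ 1/f^exponent (flat below 1 Hz)."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    amp = np.ones_like(freqs)
    nz = freqs > 0
    amp[nz] = 1.0 / np.maximum(freqs[nz], 1.0) ** (exponent / 2)
    spec = (rng.standard_normal(shape[:-1] + (freqs.size,))
            + 1j * rng.standard_normal(shape[:-1] + (freqs.size,)))
    x = np.fft.irfft(spec * amp, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _narrowband(rng, shape, fs, lo, hi):
    """Unit-RMS band-limited noise."""
    x = rng.standard_normal(shape)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _subject_patterns(config: SynthConfig, rng):
    patterns = {}
    for c, p in config.class_patterns.items():
        shift = config.subject_shift_sd * rng.standard_normal(config.C) / np.sqrt(config.C)
        q = p + shift
        patterns[c] = q / np.linalg.norm(q)
    gain = float(np.exp(config.subject_shift_sd * rng.standard_normal()))
    return patterns, gain


def make_dataset(config: SynthConfig) -> list[EpochSet]:
    """One EpochSet per (subject, session); labels balanced across classes.

    A subject's perturbed patterns and gain are shared by all their sessions
    (only the noise and source realizations differ), matching the
    same-subject-different-day structure of multi-session recordings.
    """
    root = np.random.default_rng(config.seed)
    classes = sorted(config.class_bands)
    T = config.n_samples
    out = []
    for s in range(config.n_subjects):
        rng = np.random.default_rng(root.integers(2 ** 31))
        patterns, gain = _subject_patterns(config, rng)
        for sess in range(config.n_sessions):
            n = config.trials_per_class * len(classes)
            data = np.empty((n, config.C, T))
            labels = np.empty(n, dtype=int)
            i = 0
            for c in classes:
                lo, hi = config.class_bands[c]
                for _ in range(config.trials_per_class):
                    pink = _pink_noise(rng, (config.C, T), config.fs, config.pink_exponent)
                    white = rng.standard_normal((config.C, T))
                    bg = ((1 - config.white_fraction) * pink
                          + config.white_fraction * white)
                    src = _narrowband(rng, (T,), config.fs, lo, hi)
                    # density-based scaling: at the most-loaded channel the
                    # in-band PSD elevation is snr^2 relative to a 4-Hz
                    # reference band, independent of the rhythm's bandwidth
                    amp = (config.snr * gain * np.sqrt((hi - lo) / 4.0)
                           / np.abs(patterns[c]).max())
                    data[i] = bg + amp * np.outer(patterns[c], src)
                    labels[i] = c
                    i += 1
            perm = rng.permutation(n)
            out.append(EpochSet(data=data[perm], labels=labels[perm], fs=config.fs,
                                subject_id=f"S{s + 1}", session_id=str(sess + 1)))
    return out


def planted_covariance_class(config: SynthConfig, Sigma: np.ndarray,
                             n_trials: int | None = None,
                             label: int = 1) -> EpochSet:
    """Zero-mean Gaussian trials with expected channel covariance ``Sigma``."""
    Sigma = np.asarray(Sigma, dtype=float)
    if Sigma.shape != (config.C, config.C) or not np.allclose(Sigma, Sigma.T):
        raise ValueError("Sigma must be symmetric C x C")
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as err:
        raise ValueError("Sigma must be positive definite") from err
    n = n_trials if n_trials is not None else config.trials_per_class
    rng = np.random.default_rng(config.seed)
    data = np.einsum("cd,idt->ict", L, rng.standard_normal((n, config.C, config.n_samples)))
    return EpochSet(data=data, labels=np.full(n, label, dtype=int), fs=config.fs,
                    subject_id="planted", session_id="1")
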