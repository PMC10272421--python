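"""Desk-scale reference experiments on synthetic EEG.

These are the package's standard scaled-down studies: every quantity is
recomputed from scratch on seeded synthetic data so the full pipeline can be
exercised on a single CPU in minutes.  Problem sizes (8 channels, 64 Hz,
4-s trials, tens of trials per class) are reduced relative to a full
22-channel/250-Hz recording session; the architectures either keep their
full-size roster (the classifier, the default generator contract) or use the
documented ``small`` variants (GAN training studies).

The functions here are shared by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.spatial.distance import pdist, squareform

from .cspselect import SparseCSPSelector, SparseSpatialFilter
from .crnndf import ClassifierSpec, LossConfig, predict, train_crnn_df
from .evaluation import (accuracy, augment, covariance_correlation,
                         leakage_audit, loso_split)
from .fbgan import (DiscriminatorSpec, GANTrainingConfig, GeneratorSpec,
                    generate, train_fbgan)
from .synth import SynthConfig, make_dataset, planted_covariance_class

#: Filter bank for 64-Hz scaled data (bands above 28 Hz would sit at Nyquist).
BANDS_64HZ = ((1, 4), (4, 8), (8, 12), (12, 16), (16, 20), (20, 24), (24, 28))


def synth_classification_config(seed: int) -> SynthConfig:
    """The scaled 4-class dataset for classifier studies: one subject,
    20 trials/class, 8 channels, 64 Hz, 4-s trials, source-to-background
    SNR 1 (a realistic band-power effect size)."""
    return SynthConfig(n_subjects=1, trials_per_class=20, C=8, fs=64.0,
                       T_seconds=4.0, snr=1.0, subject_shift_sd=0.0, seed=seed)


def scaled_loss_config(lambda_center: float, seed: int) -> LossConfig:
    """Classifier schedule for the scaled dataset: 90 epochs covers six
    center-update cycles (epochs 15, 30, ..., 90), long enough for the
    center-distance term to keep contracting clusters after the
    classification loss has saturated; the learning rate is raised to 1e-3
    to converge within that budget at this problem size."""
    return LossConfig(lambda_center=lambda_center, lr=1e-3, batch_size=32,
                      n_epochs=90, seed=seed)


def within_between_ratio(features: np.ndarray, labels: np.ndarray) -> float:
    """Mean within-class pairwise feature distance over mean between-class."""
    D = squareform(pdist(features))
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices_from(D, 1)
    return float(D[iu][same[iu]].mean() / D[iu][~same[iu]].mean())


def crnn_synth_study(seed: int, lambda_center: float = 0.1):
    """Train the full-roster CRNN-DF on the scaled dataset.

    Returns (training accuracy %, within/between feature-distance ratio).
    """
    ds = make_dataset(synth_classification_config(1000 + seed))[0]
    config = scaled_loss_config(lambda_center, seed)
    model, _, history = train_crnn_df(ds, config=config,
                                      spec=ClassifierSpec(n_classes=4))
    _, feats = predict(model, ds)
    return history[-1]["accuracy"], within_between_ratio(feats, ds.labels)


def lambda_pairing(seed: int):
    """Paired (same data, same seed) ratios for lambda = 0.1 and 0."""
    _, r_df = crnn_synth_study(seed, 0.1)
    _, r_plain = crnn_synth_study(seed, 0.0)
    return r_df, r_plain


def planted_sigma(C: int, seed: int = 77) -> np.ndarray:
    """A structured SPD channel covariance: rank-2 factors plus a ridge,
    normalized to unit diagonal."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((C, 2))
    S = A @ A.T + 0.3 * np.eye(C)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def fbgan_covariance_study(seed: int, n_epochs: int = 40) -> float:
    """Train the small FBGAN on a planted-covariance class (8 ch, 1 s at
    64 Hz, 60 trials) and return the Pearson correlation between the real
    and generated normalized channel covariances (upper triangle).

    The sparse spatial filter handed to the FB discriminator is the top-4
    eigenvector basis of the planted covariance (a synthetic stand-in for a
    CSP-derived filter on this single-class fixture), assigned to one broad
    2-28 Hz band.
    """
    C, T, fs = 8, 64, 64.0
    Sigma = planted_sigma(C)
    cfg = SynthConfig(n_subjects=1, trials_per_class=60, C=C, fs=fs,
                      T_seconds=1.0, seed=2000 + seed)
    real = planted_covariance_class(cfg, Sigma, n_trials=60)
    _, evecs = np.linalg.eigh(Sigma)
    W = SparseSpatialFilter(W=evecs[:, -4:],
                            provenance=[(0, 1, k) for k in range(4)],
                            band_of_column=np.zeros(4, dtype=int))
    config = GANTrainingConfig(lr=1e-3, batch_size=5, n_epochs=n_epochs, seed=seed)
    gen, _ = train_fbgan(real, W, config,
                         gen_spec=GeneratorSpec.small(C, T, noise_dim=32),
                         raw_spec=DiscriminatorSpec.small("raw", C, T),
                         fb_spec=DiscriminatorSpec.small("fb", 4, T),
                         fs=fs, bands=((2.0, 28.0),))
    fake = generate(gen, 200, seed=seed)
    return covariance_correlation(real.data, fake.data)


def fbgan_psd_study(seed: int, n_epochs: int = 30):
    """Train the small FBGAN on a narrowband 8-12 Hz class and return the
    (real peak Hz, generated peak Hz) of the trial-mean Welch PSD."""
    C, T, fs = 8, 128, 64.0
    cfg = SynthConfig(n_subjects=1, trials_per_class=50, C=C, fs=fs,
                      T_seconds=2.0, class_bands={1: (8.0, 12.0)}, snr=3.0,
                      subject_shift_sd=0.0, seed=3000 + seed)
    ds = make_dataset(cfg)[0]
    rng = np.random.default_rng(seed)
    Wm, _ = np.linalg.qr(rng.standard_normal((C, 4)))
    W = SparseSpatialFilter(W=Wm, provenance=[(0, 1, k) for k in range(4)],
                            band_of_column=np.zeros(4, dtype=int))
    config = GANTrainingConfig(lr=1e-3, batch_size=5, n_epochs=n_epochs, seed=seed)
    gen, _ = train_fbgan(ds, W, config,
                         gen_spec=GeneratorSpec.small(C, T, noise_dim=32),
                         raw_spec=DiscriminatorSpec.small("raw", C, T),
                         fb_spec=DiscriminatorSpec.small("fb", 4, T),
                         fs=fs, bands=((8.0, 12.0),))
    fake = generate(gen, 100, seed=seed + 1)

    def peak(data):
        f, P = sps.welch(data.mean(axis=1), fs=fs, nperseg=64)
        return float(f[np.argmax(P.mean(axis=0))])

    return peak(ds.data), peak(fake.data)


def augmentation_benchmark(seed: int):
    """End-to-end LOSO benchmark with subject-specific shifts.

    Three subjects x two sessions (10 trials/class/session, shift sd 0.8);
    the target's first session feeds the sparse-CSP fit and per-class GAN
    training, 10 generated trials per class are mixed into the pooled
    non-target training set, and the classifier is evaluated on the target.
    Returns (accuracy without augmentation %, with augmentation %).
    """
    cfg = SynthConfig(n_subjects=3, n_sessions=2, trials_per_class=10, C=8,
                      fs=64.0, T_seconds=4.0, snr=1.0, subject_shift_sd=0.8,
                      seed=4000 + seed)
    ds = make_dataset(cfg)
    split = loso_split(ds, "S3", seed=seed)
    sess1 = next(e for e in ds if e.subject_id == "S3" and e.session_id == "1")
    sel = SparseCSPSelector(m=2, lam=0.05, fs=64.0, bands=BANDS_64HZ,
                            seed=seed).fit(sess1.data, sess1.labels)
    n_sel = sel.sparse_filter_.n_sel
    use_fb = n_sel >= 4
    gens = []
    for c in (1, 2, 3, 4):
        Xc = sess1.data[sess1.labels == c]
        config = GANTrainingConfig(lr=1e-3, batch_size=5, n_epochs=40,
                                   seed=seed * 10 + c)
        gen, _ = train_fbgan(
            Xc, sel.sparse_filter_ if use_fb else None, config,
            gen_spec=GeneratorSpec.small(8, 256, noise_dim=32),
            raw_spec=DiscriminatorSpec.small("raw", 8, 256),
            fb_spec=DiscriminatorSpec.small("fb", n_sel, 256) if use_fb else None,
            fs=64.0, bands=BANDS_64HZ)
        gens.append(generate(gen, 10, seed=seed * 10 + c, class_label=c,
                             subject_id="S3"))
    aug_split = augment(split, gens, 40, seed=seed)
    assert leakage_audit(aug_split)
    out = {}
    for name, trials in (("noaug", split.train), ("aug", aug_split.train)):
        config = LossConfig(lambda_center=0.1, lr=1e-3, batch_size=32,
                            n_epochs=30, seed=seed)
        model, _, _ = train_crnn_df(trials.data, config=config,
                                    spec=ClassifierSpec(n_classes=4),
                                    labels=trials.labels)
        pred, _ = predict(model, split.test.data,
                          classes=np.unique(trials.labels))
        out[name] = accuracy(pred, split.test.labels)
    return out["noaug"], out["aug"]
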