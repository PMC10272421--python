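"""Leave-one-subject-out evaluation, augmentation mixing and quality metrics.

A LOSO split pools every trial of every non-target subject (all sessions)
into a seeded, shuffled training set and leaves the target subject's trials
untouched as the test set; with 9 subjects of 2 x 288 trials this is
4608 / 576.  Augmentation appends generator output (flagged synthetic,
subject == target) to the training set only.  Per-trial provenance
identifiers travel with both sets so leakage can be audited directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .fbgan import GeneratedEpochSet
from .preprocess import EpochSet


@dataclass
class TaggedTrials:
    """Trials plus (subject, session, trial, synthetic) provenance rows."""

    data: np.ndarray
    labels: np.ndarray
    ids: list                  # (subject, session, trial_index, synthetic)

    def __len__(self):
        return len(self.labels)


@dataclass
class LOSOSplit:
    train: TaggedTrials
    test: TaggedTrials
    target_id: str


def _pool(subject_sets: list[EpochSet]):
    data, labels, ids = [], [], []
    for es in subject_sets:
        data.append(es.data)
        labels.append(es.labels)
        ids.extend((es.subject_id, es.session_id, i, False)
                   for i in range(es.n_trials))
    return np.concatenate(data), np.concatenate(labels), ids


def loso_split(dataset: list[EpochSet], target_subject: str, seed: int = 0) -> LOSOSplit:
    """Pool and shuffle all non-target trials; keep target trials as test."""
    subjects = {es.subject_id for es in dataset}
    if len(subjects) < 2:
        raise ValueError("need at least two subjects")
    if target_subject not in subjects:
        raise ValueError(f"unknown subject {target_subject!r}")
    train_sets = [es for es in dataset if es.subject_id != target_subject]
    test_sets = [es for es in dataset if es.subject_id == target_subject]
    Xtr, ytr, ids_tr = _pool(train_sets)
    Xte, yte, ids_te = _pool(test_sets)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ytr))
    train = TaggedTrials(Xtr[perm], ytr[perm], [ids_tr[i] for i in perm])
    return LOSOSplit(train=train, test=TaggedTrials(Xte, yte, ids_te),
                     target_id=target_subject)


def augment(split: LOSOSplit, generated: list[GeneratedEpochSet], n_aug: int,
            seed: int = 0) -> LOSOSplit:
    """Append n_aug/4 generated trials per class to the training set and
    reshuffle; the test set is untouched."""
    if n_aug == 0:
        return split
    classes = sorted({g.class_label for g in generated})
    if n_aug % len(classes):
        raise ValueError(f"n_aug={n_aug} not divisible by {len(classes)} classes")
    per_class = n_aug // len(classes)
    test_classes = set(np.unique(split.test.labels))
    if not test_classes <= set(classes):
        raise ValueError(
            f"generated sets cover classes {classes}, test has {sorted(test_classes)}")
    add_X, add_y, add_ids = [], [], []
    for c in classes:
        pool = [g for g in generated if g.class_label == c]
        avail = sum(g.n for g in pool)
        if avail < per_class:
            raise ValueError(
                f"class {c}: need {per_class} generated trials, have {avail}")
        stock = np.concatenate([g.data for g in pool])[:per_class]
        add_X.append(stock)
        add_y.append(np.full(per_class, c, dtype=int))
        subj = pool[0].subject_id or split.target_id
        add_ids.extend((subj, "synthetic", i, True) for i in range(per_class))
    X = np.concatenate([split.train.data] + add_X)
    y = np.concatenate([split.train.labels] + add_y)
    ids = split.train.ids + add_ids
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(y))
    train = TaggedTrials(X[perm], y[perm], [ids[i] for i in perm])
    return LOSOSplit(train=train, test=split.test, target_id=split.target_id)


def leakage_audit(split: LOSOSplit) -> bool:
    """True when no real (subject, session, trial) identifier appears in both
    sets and every synthetic trial belongs to the target subject."""
    train_real = {t[:3] for t in split.train.ids if not t[3]}
    test_real = {t[:3] for t in split.test.ids if not t[3]}
    if train_real & test_real:
        return False
    return all(t[0] == split.target_id for t in split.train.ids if t[3])


def accuracy(predicted, true) -> float:
    """Percent correct."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.size == 0:
        raise ValueError("empty input")
    if predicted.shape != true.shape:
        raise ValueError("length mismatch")
    return 100.0 * float((predicted == true).mean())


@dataclass
class QualityReport:
    channels: list
    time_avg_real: np.ndarray       # (len(channels), samples)
    time_avg_fake: np.ndarray
    spec_freqs: np.ndarray
    spec_times: np.ndarray
    psd_real_db: np.ndarray         # (freqs, times)
    psd_fake_db: np.ndarray
    cov_real: np.ndarray            # unit-diagonal normalized covariance
    cov_fake: np.ndarray
    cov_correlation: float


def _mean_spectrogram(data: np.ndarray, fs: float, fmin=1.0, fmax=38.0,
                      nperseg=128):
    avg = data.mean(axis=1)                          # channel-average per trial
    f, t, S = sps.spectrogram(avg, fs=fs, nperseg=min(nperseg, avg.shape[-1]))
    S = S.mean(axis=0)                               # trial average
    keep = (f >= fmin) & (f <= fmax)
    return f[keep], t, 10 * np.log10(S[keep] + 1e-20)


def _normalized_covariance(data: np.ndarray) -> np.ndarray:
    """Trial-averaged channel correlation matrix (unit diagonal)."""
    covs = []
    for trial in data:
        x = trial - trial.mean(axis=1, keepdims=True)
        c = x @ x.T
        d = np.sqrt(np.diag(c))
        covs.append(c / np.outer(d, d))
    return np.mean(covs, axis=0)


def quality_report(real: EpochSet, fake, channels=("C3", "Cz", "C4")) -> QualityReport:
    """Time/frequency/spatial comparison of real and generated trials."""
    fake_data = (fake.data if isinstance(fake, (EpochSet, GeneratedEpochSet))
                 else np.asarray(fake))
    if fake_data.shape[1:] != real.data.shape[1:]:
        raise ValueError("real and generated trials must share (channels, samples)")
    if real.channel_names is not None:
        names = list(real.channel_names)
        idx = []
        for ch in channels:
            if ch not in names:
                raise KeyError(f"channel {ch!r} not found")
            idx.append(names.index(ch))
    else:
        idx = [ch for ch in range(min(len(channels), real.n_channels))]
        channels = [str(i) for i in idx]
    time_real = real.data[:, idx].mean(axis=0)
    time_fake = fake_data[:, idx].mean(axis=0)
    f, t, psd_real = _mean_spectrogram(real.data, real.fs)
    _, _, psd_fake = _mean_spectrogram(fake_data, real.fs)
    cov_real = _normalized_covariance(real.data)
    cov_fake = _normalized_covariance(fake_data)
    iu = np.triu_indices_from(cov_real, k=1)
    corr = float(np.corrcoef(cov_real[iu], cov_fake[iu])[0, 1])
    return QualityReport(channels=list(channels), time_avg_real=time_real,
                         time_avg_fake=time_fake, spec_freqs=f, spec_times=t,
                         psd_real_db=psd_real, psd_fake_db=psd_fake,
                         cov_real=cov_real, cov_fake=cov_fake,
                         cov_correlation=corr)


def covariance_correlation(real_data: np.ndarray, fake_data: np.ndarray) -> float:
    """Pearson correlation of the strictly-upper triangles of the normalized
    channel covariance matrices."""
    cr = _normalized_covariance(np.asarray(real_data))
    cf = _normalized_covariance(np.asarray(fake_data))
    iu = np.triu_indices_from(cr, k=1)
    return float(np.corrcoef(cr[iu], cf[iu])[0, 1])


def confusion_matrix(predicted, true, classes) -> np.ndarray:
    classes = np.asarray(classes)
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for p, t in zip(np.asarray(predicted), np.asarray(true)):
        cm[np.searchsorted(classes, t), np.searchsorted(classes, p)] += 1
    return cm


def write_manifest(path, **entries):
    """JSON run manifest: configuration, seeds and input checksums."""
    import hashlib
    import json

    def convert(v):
        if isinstance(v, np.ndarray):
            return hashlib.sha256(np.ascontiguousarray(v).tobytes()).hexdigest()
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    with open(path, "w") as f:
        json.dump({k: convert(v) for k, v in entries.items()}, f, indent=2)


def sweep(param: str, values, run_fn, subjects) -> pd.DataFrame:
    """One full pipeline run per value: ``run_fn(param_value, subject) ->
    accuracy``.  Returns a tidy table (value, per-subject accuracy, mean,
    population std)."""
    if len(values) == 0:
        raise ValueError("values must be non-empty")
    rows = []
    for v in values:
        accs = {s: run_fn(v, s) for s in subjects}
        vals = np.array(list(accs.values()), dtype=float)
        rows.append({param: v, **accs, "mean": vals.mean(),
                     "std": vals.std(ddof=0)})
    return pd.DataFrame(rows)
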