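"""Convolutional-recurrent classifier with discriminative-feature training.

Architecture: a single spatial convolution spanning all C channels with a
C x 45 kernel (stride 1), a 1 x 75 max-pool with stride 10, a 2-layer LSTM
with hidden size 64 and dropout 0.5, and a linear head over the final
hidden state.  The 64-d final hidden state is the feature vector ``v`` used
by the center-distance loss.

Training minimizes ``cross-entropy + lambda * L_cen`` where ``L_cen`` is
the mean squared distance between each feature vector and its class
centroid.  Centers are initialized from the whole training set with a
shrunken mean (denominator ``1 + count``, as an intentional pull toward the
origin for rare classes; a plain mean is available), and every
``update_every`` epochs they are re-estimated from the current features and
then pushed a fixed step ``alpha`` away from the global center mean, which
expands between-class distances while the loss contracts within-class
scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .preprocess import EpochSet


@dataclass
class ClassifierSpec:
    conv_kernel_t: int = 45
    conv_filters: int = 64
    pool_kernel: int = 75
    pool_stride: int = 10
    lstm_layers: int = 2
    hidden: int = 64
    dropout: float = 0.5
    n_classes: int = 4

    def __post_init__(self):
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    def min_samples(self):
        return self.conv_kernel_t + self.pool_kernel

    def sequence_length(self, T: int) -> int:
        conv_t = T - self.conv_kernel_t + 1
        if conv_t < self.pool_kernel:
            raise ValueError(
                f"T={T} too small: conv leaves {conv_t} samples, pooling needs "
                f">= {self.pool_kernel} (minimum T is {self.min_samples() - 1 + 1})")
        return (conv_t - self.pool_kernel) // self.pool_stride + 1


@dataclass
class CenterBank:
    centers: np.ndarray          # (n_classes, feature_dim)
    classes: np.ndarray          # class labels, row order
    alpha: float = 0.02
    update_every: int = 15

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.classes = np.asarray(self.classes)
        if not np.isfinite(self.centers).all():
            raise ValueError("centers must be finite")

    def center_of(self, label):
        return self.centers[np.searchsorted(self.classes, label)]


@dataclass
class LossConfig:
    lambda_center: float = 0.1
    lr: float = 1e-4
    batch_size: int = 32
    n_epochs: int = 200
    seed: int = 0
    alpha: float = 0.02
    update_every: int = 15
    betas: tuple = (0.9, 0.999)
    center_init: str = "shrunk"   # 'shrunk' (1 + count denominator) or 'mean'

    def __post_init__(self):
        if self.lambda_center < 0:
            raise ValueError("lambda_center must be >= 0")


class CRNN(nn.Module):
    """conv(C x 45) -> ReLU -> maxpool(1x75 /10) -> dropout -> LSTM x2 ->
    dropout -> linear head.  ``forward`` returns logits; ``forward_features``
    returns (features, logits)."""

    def __init__(self, spec: ClassifierSpec, C: int, T: int, rng, dtype=np.float32):
        super().__init__()
        self.spec = spec
        self.C, self.T = C, T
        self.seq_len = spec.sequence_length(T)   # validates T
        self.conv = nn.Conv2d(1, spec.conv_filters, (C, spec.conv_kernel_t), (1, 1),
                              rng=rng, dtype=dtype)
        self.act = nn.ReLU()
        self.pool = nn.MaxPool2d((1, spec.pool_kernel), (1, spec.pool_stride))
        self.drop_in = nn.Dropout(spec.dropout, rng)
        self.lstm = nn.LSTM(spec.conv_filters, spec.hidden, spec.lstm_layers, rng,
                            dropout=spec.dropout, dtype=dtype)
        self.drop_out = nn.Dropout(spec.dropout, rng)
        self.head = nn.Linear(spec.hidden, spec.n_classes, rng, dtype=dtype)

    def forward_features(self, x):
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[2] != self.C or x.shape[3] != self.T:
            raise ValueError(
                f"expected trials of shape ({self.C}, {self.T}), got {x.shape[2:]}")
        h = self.pool(self.act(self.conv(x)))           # (B, F, 1, L)
        B = h.shape[0]
        h = self.drop_in(h)
        seq = h[:, :, 0, :].transpose(0, 2, 1)          # (B, L, F)
        out_seq = self.lstm(np.ascontiguousarray(seq))
        self._out_shape = out_seq.shape
        v = out_seq[:, -1, :]                           # final hidden state
        v_d = self.drop_out(v)
        logits = self.head(v_d)
        return v, logits

    def forward(self, x):
        return self.forward_features(x)[1]

    def backward_from(self, grad_logits, grad_features=None):
        """Backprop given d(loss)/d(logits) and optionally d(loss)/d(v)."""
        gv = self.drop_out.backward(self.head.backward(grad_logits))
        if grad_features is not None:
            gv = gv + grad_features.astype(gv.dtype)
        gseq = np.zeros(self._out_shape, dtype=gv.dtype)
        gseq[:, -1, :] = gv
        g = self.lstm.backward(gseq)
        g = g.transpose(0, 2, 1)[:, :, None, :]         # (B, F, 1, L)
        g = self.drop_in.backward(g)
        g = self.conv.backward(self.act.backward(self.pool.backward(g)))
        return g


# ---------------------------------------------------------------------------
# operations


def build_crnn(spec: ClassifierSpec, C: int, T: int, seed: int = 0) -> CRNN:
    rng = np.random.default_rng(seed)
    return CRNN(spec, C, T, rng)


def init_centers(features: np.ndarray, labels: np.ndarray, classes=None,
                 alpha: float = 0.02, update_every: int = 15,
                 mode: str = "shrunk") -> CenterBank:
    """Per-class centroids; 'shrunk' divides by (1 + count) so an empty class
    gets the zero vector, 'mean' is the plain class mean."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    classes = np.sort(np.asarray(classes))
    centers = np.zeros((len(classes), features.shape[1]))
    for i, c in enumerate(classes):
        mask = labels == c
        total = features[mask].sum(axis=0) if mask.any() else 0.0
        if mode == "shrunk":
            centers[i] = total / (1.0 + mask.sum())
        elif mode == "mean":
            centers[i] = total / mask.sum() if mask.any() else 0.0
        else:
            raise ValueError("mode must be 'shrunk' or 'mean'")
    return CenterBank(centers=centers, classes=classes, alpha=alpha,
                      update_every=update_every)


def center_loss(features: np.ndarray, labels: np.ndarray, bank: CenterBank):
    """Mean squared Euclidean distance to the class centroid.

    Returns (loss, gradient w.r.t. features); centers are schedule-updated,
    not gradient-trained.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[1] != bank.centers.shape[1]:
        raise ValueError("feature dimension does not match the center bank")
    rows = np.searchsorted(bank.classes, labels)
    diff = features - bank.centers[rows]
    b = features.shape[0]
    loss = float((diff ** 2).sum() / b)
    grad = 2.0 * diff / b
    return loss, grad


def expand_centers(bank: CenterBank, features_by_class: dict | None = None,
                   mode: str = "shrunk") -> CenterBank:
    """Push each center ``alpha`` along the unit vector from the global center
    mean toward itself; centers coincident with the mean stay put.

    When ``features_by_class`` is given, centers are first re-estimated from
    those features (tracking feature drift), then moved.
    """
    centers = bank.centers.copy()
    if features_by_class is not None:
        for i, c in enumerate(bank.classes):
            feats = np.asarray(features_by_class.get(c, np.empty((0, centers.shape[1]))))
            total = feats.sum(axis=0) if len(feats) else 0.0
            denom = (1.0 + len(feats)) if mode == "shrunk" else max(len(feats), 1)
            centers[i] = total / denom
    vc = centers.mean(axis=0)
    moved = centers.copy()
    for i in range(len(centers)):
        d = centers[i] - vc
        norm = np.linalg.norm(d)
        if norm > 0:
            moved[i] = centers[i] + bank.alpha * d / norm
    return replace(bank, centers=moved)


def total_loss(logits: np.ndarray, labels: np.ndarray, l_cen: float,
               lambda_center: float):
    """Cross-entropy plus ``lambda_center * l_cen``; returns (loss, grad_logits)."""
    ce, grad = nn.softmax_cross_entropy(logits, labels)
    return ce + lambda_center * l_cen, grad


def _as_xy(train, labels=None):
    if isinstance(train, EpochSet):
        return train.data, train.labels
    return np.asarray(train), np.asarray(labels)


def _batch_features(model: CRNN, X, batch_size=64):
    model.eval()
    feats, logits = [], []
    for i in range(0, len(X), batch_size):
        v, lg = model.forward_features(X[i:i + batch_size].astype(np.float32))
        feats.append(v)
        logits.append(lg)
    model.train()
    return np.concatenate(feats), np.concatenate(logits)


def train_crnn_df(train, config: LossConfig | None = None,
                  spec: ClassifierSpec | None = None, labels=None,
                  model: CRNN | None = None):
    """Joint training with classification + center-distance loss.

    Returns (model, bank, history); history is a list of per-epoch dicts
    with loss components, training accuracy and center-update bookkeeping.
    """
    config = config or LossConfig()
    X, y = _as_xy(train, labels)
    X = np.asarray(X, dtype=np.float32)
    if len(X) < config.batch_size:
        raise ValueError(
            f"need at least batch_size={config.batch_size} trials, got {len(X)}")
    classes = np.unique(y)
    if spec is None:
        spec = ClassifierSpec(n_classes=len(classes))
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = CRNN(spec, X.shape[1], X.shape[2], rng)
    y_idx = np.searchsorted(classes, y)

    # center initialization from the whole training set, before epoch 1
    feats0, _ = _batch_features(model, X)
    bank = init_centers(feats0, y, classes=classes, alpha=config.alpha,
                        update_every=config.update_every, mode=config.center_init)

    opt = nn.Adam(model.parameters(), lr=config.lr, betas=config.betas)
    history = []
    n = len(X)
    for epoch_i in range(1, config.n_epochs + 1):
        perm = rng.permutation(n)
        ep_ce = ep_cen = 0.0
        correct = 0
        n_batches = 0
        for start in range(0, n - config.batch_size + 1, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb, yb = X[idx], y_idx[idx]
            v, logits = model.forward_features(xb)
            l_cen, g_v = center_loss(v, y[idx], bank)
            loss, g_logits = total_loss(logits, yb, l_cen, config.lambda_center)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch_i}, batch {n_batches}")
            model.zero_grad()
            model.backward_from(g_logits, config.lambda_center * g_v)
            opt.step()
            ce = loss - config.lambda_center * l_cen
            ep_ce += ce
            ep_cen += l_cen
            correct += int((logits.argmax(axis=1) == yb).sum())
            n_batches += 1
        seen = n_batches * config.batch_size
        entry = {
            "epoch": epoch_i,
            "ce": ep_ce / n_batches,
            "l_cen": ep_cen / n_batches,
            "loss": (ep_ce + config.lambda_center * ep_cen) / n_batches,
            "accuracy": 100.0 * correct / seen,
            "centers_updated": False,
        }
        if config.update_every > 0 and epoch_i % config.update_every == 0:
            feats, _ = _batch_features(model, X)
            by_class = {c: feats[y == c] for c in classes}
            bank = expand_centers(bank, by_class, mode=config.center_init)
            entry["centers_updated"] = True
        history.append(entry)
    return model, bank, history


def predict(model: CRNN, epochs, classes=None, batch_size=64):
    """Argmax class per trial plus the 64-d feature vectors."""
    X = epochs.data if isinstance(epochs, EpochSet) else np.asarray(epochs)
    feats, logits = _batch_features(model, X.astype(np.float32), batch_size)
    idx = logits.argmax(axis=1)
    if classes is not None:
        labels = np.asarray(classes)[idx]
    else:
        labels = idx
    return labels, feats


def save_classifier(path, model: CRNN, bank: CenterBank, config: LossConfig):
    """One archive holding architecture, weights, centers, config and seed."""
    import json
    from dataclasses import asdict
    from pathlib import Path
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"spec": asdict(model.spec), "C": model.C, "T": model.T,
            "config": asdict(config),
            "bank": {"classes": bank.classes.tolist(), "alpha": bank.alpha,
                     "update_every": bank.update_every}}
    np.savez(path, __meta__=json.dumps(meta), __centers__=bank.centers,
             **model.state_dict())


def load_classifier(path):
    import json
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        centers = archive["__centers__"]
        state = {k: archive[k] for k in archive.files
                 if k not in ("__meta__", "__centers__")}
    spec = ClassifierSpec(**meta["spec"])
    config = LossConfig(**{**meta["config"],
                           "betas": tuple(meta["config"]["betas"])})
    model = build_crnn(spec, meta["C"], meta["T"], seed=config.seed)
    model.load_state_dict(state)
    bank = CenterBank(centers=centers,
                      classes=np.asarray(meta["bank"]["classes"]),
                      alpha=meta["bank"]["alpha"],
                      update_every=meta["bank"]["update_every"])
    return model, bank, config


def export_embeddings(path, model: CRNN, epochs: EpochSet, classes=None):
    """Write (trial_id, subject, label, 64 feature columns) as CSV for
    downstream 2-D embedding (e.g. t-SNE)."""
    import pandas as pd
    labels, feats = predict(model, epochs, classes=classes)
    frame = pd.DataFrame(feats, columns=[f"f{i}" for i in range(feats.shape[1])])
    frame.insert(0, "label", epochs.labels)
    frame.insert(0, "subject", epochs.subject_id)
    frame.insert(0, "trial_id", np.arange(epochs.n_trials))
    frame.to_csv(path, index=False)
    return frame


class CRNNDFClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style wrapper around the CRNN with discriminative-feature loss.

    ``fit(X, y)`` with X of shape (n_trials, channels, samples).  Fitted
    attributes: ``model_``, ``centers_``, ``history_``, ``classes_``.
    ``transform`` returns the 64-d feature embedding for export.
    """

    def __init__(self, lambda_center=0.1, alpha=0.02, update_every=15,
                 lr=1e-4, batch_size=32, n_epochs=200, conv_filters=64,
                 hidden=64, lstm_layers=2, dropout=0.5, center_init="shrunk",
                 seed=0):
        self.lambda_center = lambda_center
        self.alpha = alpha
        self.update_every = update_every
        self.lr = lr
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.conv_filters = conv_filters
        self.hidden = hidden
        self.lstm_layers = lstm_layers
        self.dropout = dropout
        self.center_init = center_init
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        spec = ClassifierSpec(conv_filters=self.conv_filters, hidden=self.hidden,
                              lstm_layers=self.lstm_layers, dropout=self.dropout,
                              n_classes=len(self.classes_))
        config = LossConfig(lambda_center=self.lambda_center, lr=self.lr,
                            batch_size=self.batch_size, n_epochs=self.n_epochs,
                            seed=self.seed, alpha=self.alpha,
                            update_every=self.update_every,
                            center_init=self.center_init)
        self.model_, self.centers_, self.history_ = train_crnn_df(
            X, config=config, spec=spec, labels=y)
        return self

    def predict(self, X):
        labels, _ = predict(self.model_, X, classes=self.classes_)
        return labels

    def transform(self, X):
        _, feats = predict(self.model_, X, classes=self.classes_)
        return feats

    def score(self, X, y):
        return float((self.predict(X) == np.asarray(y)).mean())
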