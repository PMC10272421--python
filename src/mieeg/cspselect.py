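"""One-versus-rest CSP per sub-band, LASSO sparsification, sparse spatial filter.

For every filter-bank band and every class c the generalized eigenproblem
``R_c w = lambda R_rest w`` is solved on trace-normalized mean covariances;
the ``m`` leading eigenvectors per (band, class) are stacked (4 classes x
m=4 x 10 bands = 160 columns by default).  Log-normalized variance features
of all columns enter a single L1-penalized regression on the numeric class
labels; columns whose coefficients survive form the sparse spatial filter
``W_csp`` that projects trials to "FB data" (each column applied to the
trial filtered in the column's own band).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import Lasso, LassoCV

from .preprocess import BandEpochs, EpochSet, FilterBankSpec, filter_bank


@dataclass
class CovarianceSet:
    R: dict            # class label -> (channels, channels)
    n_trials: dict     # class label -> count


@dataclass
class CSPSubFilter:
    band_index: int
    target_class: int
    W: np.ndarray               # (channels, m)
    eigenvalues: np.ndarray     # (m,) descending
    m: int = 4


@dataclass
class BandFilterStack:
    """band x class grid of OVR sub-filters."""

    subfilters: list            # list over bands of list over classes of CSPSubFilter
    classes: np.ndarray
    m: int

    @property
    def n_bands(self):
        return len(self.subfilters)

    @property
    def per_band_columns(self):
        return len(self.classes) * self.m

    @property
    def n_columns(self):
        return self.n_bands * self.per_band_columns

    def column_index(self):
        """Per-column (band, class, eigenvector) provenance, in stack order."""
        out = []
        for b, band in enumerate(self.subfilters):
            for sf in band:
                for k in range(sf.m):
                    out.append((b, sf.target_class, k))
        return out

    def columns(self):
        """(channels, n_columns) matrix of all stacked columns."""
        cols = []
        for band in self.subfilters:
            for sf in band:
                cols.append(sf.W)
        return np.concatenate(cols, axis=1)


@dataclass
class FeatureMatrix:
    F: np.ndarray               # (trials, D)
    column_index: list          # per-column (band, class, eigenvector)

    @property
    def D(self):
        return self.F.shape[1]


@dataclass
class LassoSelection:
    beta: np.ndarray
    beta0: float
    lam: float
    selected: np.ndarray        # indices with beta != 0


@dataclass
class SparseSpatialFilter:
    W: np.ndarray               # (channels, n_sel)
    provenance: list            # per-column (band, class, eigenvector)
    band_of_column: np.ndarray  # band index per column

    @property
    def n_sel(self):
        return self.W.shape[1]


# ---------------------------------------------------------------------------
# operations


def mean_covariance(band_trials: np.ndarray, labels: np.ndarray, target_class) -> np.ndarray:
    """Mean of trace-normalized trial covariances for one class."""
    band_trials = np.asarray(band_trials)
    mask = np.asarray(labels) == target_class
    if not mask.any():
        raise ValueError(f"no trials of class {target_class}")
    X = band_trials[mask]
    covs = np.einsum("ict,idt->icd", X, X)
    traces = np.trace(covs, axis1=1, axis2=2)
    covs /= traces[:, None, None]
    return covs.mean(axis=0)


def covariance_set(band_trials: np.ndarray, labels: np.ndarray) -> CovarianceSet:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    R = {c: mean_covariance(band_trials, labels, c) for c in classes}
    n = {c: int((labels == c).sum()) for c in classes}
    return CovarianceSet(R=R, n_trials=n)


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-magnitude entry of each column is positive."""
    idx = np.abs(W).argmax(axis=0)
    signs = np.sign(W[idx, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    return W * signs


def csp_subfilter(R_c: np.ndarray, R_rest: np.ndarray, m: int = 4,
                  band_index: int = 0, target_class: int = 0,
                  reg: float = 1e-8) -> CSPSubFilter:
    """Leading eigenvectors of R_c w = lambda R_rest w (descending lambda).

    R_rest is ridge-conditioned with ``reg * trace`` before the solve.
    """
    R_c = np.asarray(R_c, dtype=float)
    R_rest = np.asarray(R_rest, dtype=float)
    if not (np.isfinite(R_c).all() and np.isfinite(R_rest).all()):
        raise ValueError("covariance matrices must be finite")
    n = R_c.shape[0]
    R_rest = R_rest + reg * np.trace(R_rest) * np.eye(n)
    evals, evecs = linalg.eigh(R_c, R_rest)
    # stable descending sort: eigenvalue first, original index as tie-break
    order = np.argsort(-evals, kind="stable")[:m]
    W = _fix_signs(evecs[:, order])
    return CSPSubFilter(band_index=band_index, target_class=int(target_class),
                        W=W, eigenvalues=evals[order], m=m)


def band_filter_stack(band_epochs: BandEpochs, m: int = 4,
                      classes=None, reg: float = 1e-8) -> BandFilterStack:
    """OVR sub-filters for every (band, class) pair.

    Raises if a requested class is absent from the data.
    """
    labels = band_epochs.labels
    present = np.unique(labels)
    if classes is None:
        classes = present
    else:
        classes = np.asarray(classes)
        missing = np.setdiff1d(classes, present)
        if missing.size:
            raise ValueError(f"classes {missing.tolist()} absent from the data")
    if len(present) < 2:
        raise ValueError("need at least two classes per band")
    subfilters = []
    for b in range(band_epochs.n_bands):
        trials = band_epochs.data[b]
        covs = covariance_set(trials, labels)
        band_list = []
        for c in classes:
            rest = [covs.R[k] for k in covs.R if k != c]
            R_rest = np.mean(rest, axis=0)
            band_list.append(csp_subfilter(covs.R[c], R_rest, m=m,
                                           band_index=b, target_class=c, reg=reg))
        subfilters.append(band_list)
    return BandFilterStack(subfilters=subfilters, classes=np.asarray(classes), m=m)


def csp_features(band_epochs: BandEpochs, stack: BandFilterStack,
                 var_floor: float = 1e-30) -> FeatureMatrix:
    """Log-normalized projected variance per stacked column.

    For column j in a sub-filter, f = log(var_j / sum of variances over the
    columns of the same sub-filter).  Zero variances are floored at
    ``var_floor`` (degenerate flat projections).
    """
    n_trials = band_epochs.n_trials
    feats = []
    index = []
    for b, band_list in enumerate(stack.subfilters):
        trials = band_epochs.data[b]          # (trials, C, T)
        for sf in band_list:
            proj = np.einsum("cm,ict->imt", sf.W, trials)   # (trials, m, T)
            var = proj.var(axis=2)
            var = np.maximum(var, var_floor)
            norm = var / var.sum(axis=1, keepdims=True)
            feats.append(np.log(norm))
            index.extend((b, sf.target_class, k) for k in range(sf.m))
    F = np.concatenate(feats, axis=1)
    assert F.shape == (n_trials, stack.n_columns)
    return FeatureMatrix(F=F, column_index=index)


def lasso_select(F: FeatureMatrix | np.ndarray, labels: np.ndarray,
                 lam: float | str = "auto", standardize: bool = True,
                 ovr: bool = False, cv: int = 5, seed: int = 0) -> LassoSelection:
    """L1-penalized least squares on numeric class labels (Eq.-style objective
    ``(1/2N)||y - b0 - F b||^2 + lam * ||b||_1``).

    ``lam='auto'`` picks the penalty by ``cv``-fold cross-validated prediction
    error over a logarithmic grid.  ``ovr=True`` fits one lasso per class
    (one-vs-rest indicator targets) and reports the union of supports with
    per-feature max-|beta| coefficients.
    """
    X = F.F if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=float)
    y = np.asarray(labels, dtype=float)
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    if isinstance(lam, str):
        if lam != "auto":
            raise ValueError("lam must be a positive number or 'auto'")
    elif lam <= 0:
        raise ValueError("lambda must be positive")

    def _fit(target):
        if lam == "auto":
            model = LassoCV(cv=cv, alphas=np.logspace(-4, 0, 30), random_state=seed,
                            max_iter=50_000, tol=1e-6)
            model.fit(X, target)
            return model, float(model.alpha_)
        model = Lasso(alpha=float(lam), max_iter=50_000, tol=1e-8)
        model.fit(X, target)
        return model, float(lam)

    if not ovr:
        model, alpha = _fit(y)
        beta = model.coef_.copy()
        beta0 = float(model.intercept_)
    else:
        betas = []
        alphas = []
        for c in np.unique(labels):
            model, alpha_c = _fit((labels == c).astype(float))
            betas.append(model.coef_)
            alphas.append(alpha_c)
        betas = np.stack(betas)
        pick = np.abs(betas).argmax(axis=0)
        beta = betas[pick, np.arange(betas.shape[1])]
        beta0 = 0.0
        alpha = float(np.mean(alphas))
    selected = np.nonzero(beta != 0)[0]
    return LassoSelection(beta=beta, beta0=beta0, lam=alpha, selected=selected)


def sparse_spatial_filter(selection: LassoSelection, stack: BandFilterStack) -> SparseSpatialFilter:
    """Keep exactly the stack columns whose features were selected."""
    if selection.selected.size == 0:
        raise ValueError("empty selection: decrease lambda so some features survive")
    cols = stack.columns()
    index = stack.column_index()
    sel = selection.selected
    W = cols[:, sel]
    prov = [index[j] for j in sel]
    bands = np.array([p[0] for p in prov], dtype=int)
    return SparseSpatialFilter(W=W, provenance=prov, band_of_column=bands)


def apply_sparse_filter(band_filtered_trial: np.ndarray,
                        W: SparseSpatialFilter) -> np.ndarray:
    """Project a band-decomposed trial: Z row j = w_j^T x^(band_j).

    ``band_filtered_trial`` is (bands, channels, samples); each selected
    column is applied to the trial filtered in its own originating band.
    """
    x = np.asarray(band_filtered_trial)
    if x.ndim != 3:
        raise ValueError("expected (bands, channels, samples)")
    if x.shape[1] != W.W.shape[0]:
        raise ValueError(
            f"channel mismatch: trial has {x.shape[1]}, filter expects {W.W.shape[0]}")
    Z = np.empty((W.n_sel, x.shape[2]))
    for j in range(W.n_sel):
        Z[j] = W.W[:, j] @ x[W.band_of_column[j]]
    return Z


class SparseCSPSelector(BaseEstimator, TransformerMixin):
    """Filter-bank OVR-CSP feature extractor with LASSO column selection.

    ``fit(X, y)`` takes standardized trials ``(n_trials, channels, samples)``,
    runs the filter bank, builds the CSP stack, extracts features and selects
    columns; ``transform`` returns the selected feature columns.  The fitted
    sparse spatial filter is available as ``sparse_filter_``.

    Parameters
    ----------
    m : eigenvectors retained per (band, class) sub-filter.
    lam : LASSO penalty, or 'auto' for cross-validated choice.
    bands : filter-bank band edges (defaults to the 10 standard bands).
    fs : sampling rate of the input trials (Hz).
    """

    def __init__(self, m=4, lam="auto", bands=None, fs=250.0, order=5,
                 standardize=True, ovr=False, seed=0):
        self.m = m
        self.lam = lam
        self.bands = bands
        self.fs = fs
        self.order = order
        self.standardize = standardize
        self.ovr = ovr
        self.seed = seed

    def _spec(self):
        if self.bands is None:
            return FilterBankSpec(order=self.order)
        return FilterBankSpec(bands=tuple(self.bands), order=self.order)

    def _band_epochs(self, X, y):
        epochs = EpochSet(data=np.asarray(X), labels=np.asarray(y), fs=self.fs)
        return filter_bank(epochs, self._spec())

    def fit(self, X, y):
        be = self._band_epochs(X, y)
        self.stack_ = band_filter_stack(be, m=self.m)
        feats = csp_features(be, self.stack_)
        self.selection_ = lasso_select(feats, y, lam=self.lam,
                                       standardize=self.standardize,
                                       ovr=self.ovr, seed=self.seed)
        self.sparse_filter_ = sparse_spatial_filter(self.selection_, self.stack_)
        self.feature_index_ = [feats.column_index[j] for j in self.selection_.selected]
        return self

    def transform(self, X):
        be = self._band_epochs(X, np.zeros(len(X), dtype=int))
        feats = csp_features(be, self.stack_)
        return feats.F[:, self.selection_.selected]

    def project(self, X):
        """Apply the sparse spatial filter: (n_trials, n_sel, samples)."""
        be = self._band_epochs(X, np.zeros(len(X), dtype=int))
        return np.stack([
            apply_sparse_filter(be.data[:, i], self.sparse_filter_)
            for i in range(be.n_trials)
        ])
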