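"""CSP eigenproblem, feature extraction, LASSO selection, sparse filter."""

import numpy as np
import pytest

from mieeg.cspselect import (SparseCSPSelector, apply_sparse_filter,
                             band_filter_stack, csp_features, csp_subfilter,
                             lasso_select, mean_covariance,
                             sparse_spatial_filter)
from mieeg.preprocess import BandEpochs, EpochSet, FilterBankSpec, filter_bank
from mieeg.synth import SynthConfig, make_dataset


def random_spd(n, seed):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, n))
    return A @ A.T + 0.1 * np.eye(n)


class TestMeanCovariance:
    def test_identity_trial_normalizes_to_half(self):
        trials = np.eye(2)[None]
        R = mean_covariance(trials, np.array([1]), 1)
        np.testing.assert_allclose(R, np.eye(2) / 2)

    def test_trace_is_one(self, rng):
        trials = rng.standard_normal((7, 5, 40))
        R = mean_covariance(trials, np.ones(7, dtype=int), 1)
        assert np.trace(R) == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(R, R.T)

    def test_duplicate_trials_do_not_change_mean(self, rng):
        trial = rng.standard_normal((1, 4, 30))
        R1 = mean_covariance(trial, np.array([2]), 2)
        R2 = mean_covariance(np.concatenate([trial, trial]), np.array([2, 2]), 2)
        np.testing.assert_allclose(R1, R2)

    def test_empty_class_raises(self, rng):
        with pytest.raises(ValueError, match="class 3"):
            mean_covariance(rng.standard_normal((2, 3, 10)), np.array([1, 2]), 3)


class TestCSPSubfilter:
    def test_analytic_diagonal_case(self):
        sf = csp_subfilter(np.diag([0.8, 0.2]), np.diag([0.2, 0.8]), m=2, reg=0)
        np.testing.assert_allclose(sorted(sf.eigenvalues), [0.25, 4.0], atol=1e-10)
        lead = sf.W[:, 0] / np.linalg.norm(sf.W[:, 0])
        np.testing.assert_allclose(np.abs(lead), [1.0, 0.0], atol=1e-10)

    def test_identical_classes_give_unit_eigenvalues(self):
        R = random_spd(4, 0)
        R = R / np.trace(R)
        sf = csp_subfilter(R, R, m=4, reg=0)
        np.testing.assert_allclose(sf.eigenvalues, 1.0, atol=1e-8)

    def test_leading_column_beats_random_vectors_on_rayleigh_quotient(self):
        R_c, R_rest = random_spd(4, 1), random_spd(4, 2)
        sf = csp_subfilter(R_c, R_rest, m=4, reg=0)
        w0 = sf.W[:, 0]
        best = w0 @ R_c @ w0 / (w0 @ R_rest @ w0)
        rng = np.random.default_rng(3)
        V = rng.standard_normal((100_000, 4))
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        quotients = np.einsum("ij,jk,ik->i", V, R_c, V) / np.einsum(
            "ij,jk,ik->i", V, R_rest, V)
        assert best >= quotients.max() - 1e-9

    def test_eigenvalues_sorted_descending(self):
        sf = csp_subfilter(random_spd(5, 4), random_spd(5, 5), m=4)
        assert np.all(np.diff(sf.eigenvalues) <= 1e-12)

    def test_nonfinite_input_raises(self):
        R = np.eye(2)
        R2 = np.array([[np.inf, 0], [0, 1.0]])
        with pytest.raises(ValueError, match="finite"):
            csp_subfilter(R2, R)


def _band_epochs(rng, n_trials=24, C=6, T=100, n_bands=2, n_classes=4):
    data = rng.standard_normal((n_bands, n_trials, C, T))
    labels = np.tile(np.arange(1, n_classes + 1), n_trials // n_classes)
    spec = FilterBankSpec(bands=tuple((4 * i + 1, 4 * i + 4) for i in range(n_bands)))
    return BandEpochs(data=data, spec=spec, labels=labels, fs=64.0)


class TestBandFilterStack:
    def test_column_counts(self, rng):
        be = _band_epochs(rng, n_bands=1)
        stack = band_filter_stack(be, m=4)
        assert stack.per_band_columns == 16
        assert stack.n_columns == 16
        be10 = _band_epochs(rng, n_bands=10)
        assert band_filter_stack(be10, m=4).n_columns == 160

    def test_two_class_one_eigenvector(self, rng):
        be = _band_epochs(rng, n_trials=8, n_bands=1, n_classes=2)
        stack = band_filter_stack(be, m=1)
        assert stack.n_columns == 2

    def test_absent_class_raises(self, rng):
        be = _band_epochs(rng)
        with pytest.raises(ValueError, match="absent"):
            band_filter_stack(be, classes=[1, 2, 3, 4, 9])

    def test_projected_variance_ratio_matches_eigenvalue(self, rng):
        be = _band_epochs(rng, n_trials=40, C=4)
        stack = band_filter_stack(be, m=2, reg=0)
        sf = stack.subfilters[0][0]
        trials = be.data[0]
        labels = be.labels
        c = sf.target_class
        from mieeg.cspselect import covariance_set
        covs = covariance_set(trials, labels)
        R_rest = np.mean([covs.R[k] for k in covs.R if k != c], axis=0)
        for j in range(sf.m):
            w = sf.W[:, j]
            ratio = (w @ covs.R[c] @ w) / (w @ R_rest @ w)
            assert ratio == pytest.approx(sf.eigenvalues[j], rel=1e-8)


class TestCSPFeatures:
    def test_default_dimensionality_160(self, rng):
        be = _band_epochs(rng, n_bands=10)
        stack = band_filter_stack(be, m=4)
        feats = csp_features(be, stack)
        assert feats.D == 160
        assert len(feats.column_index) == 160

    def test_equal_variance_projections_give_log_quarter(self):
        # identity sub-filter on white trials of equal per-channel variance
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 4, 20000))
        be = BandEpochs(data=x[None], labels=np.array([1]),
                        spec=FilterBankSpec(bands=((1, 4),)), fs=64.0)
        stack = band_filter_stack(_band_epochs(rng, C=4, n_bands=1), m=4)
        # overwrite the first sub-filter with identity columns
        stack.subfilters[0][0].W = np.eye(4)
        feats = csp_features(be, stack)
        np.testing.assert_allclose(feats.F[0, :4], np.log(0.25), atol=0.02)

    def test_deterministic(self, rng):
        be = _band_epochs(rng)
        stack = band_filter_stack(be, m=2)
        np.testing.assert_array_equal(csp_features(be, stack).F,
                                      csp_features(be, stack).F)


def _orthonormal_design(N=32, D=5):
    """Zero-mean columns with X^T X = N I (cosine basis, DC excluded)."""
    n = np.arange(N)
    X = np.stack([np.sqrt(2) * np.cos(np.pi * (k + 1) * (n + 0.5) / N)
                  for k in range(D)], axis=1)
    return X


class TestLassoSelect:
    def test_soft_thresholding_on_orthonormal_design(self):
        X = _orthonormal_design()
        rng = np.random.default_rng(6)
        y = rng.standard_normal(32)
        lam = 0.15
        sel = lasso_select(X, y, lam=lam, standardize=False)
        bhat = X.T @ (y - y.mean()) / len(y)
        expected = np.sign(bhat) * np.maximum(np.abs(bhat) - lam, 0.0)
        np.testing.assert_allclose(sel.beta, expected, atol=1e-6)
        np.testing.assert_array_equal(sel.selected, np.nonzero(expected)[0])

    def test_kkt_conditions_hold(self, rng):
        X = rng.standard_normal((40, 8))
        y = rng.standard_normal(40)
        lam = 0.1
        sel = lasso_select(X, y, lam=lam, standardize=True)
        Xs = (X - X.mean(0)) / X.std(0)
        resid = y - sel.beta0 - Xs @ sel.beta
        grad = Xs.T @ resid / len(y)
        zero = sel.beta == 0
        assert np.all(np.abs(grad[zero]) <= lam + 1e-6)
        np.testing.assert_allclose(grad[~zero], lam * np.sign(sel.beta[~zero]),
                                   atol=1e-6)

    def test_huge_lambda_shrinks_everything(self, rng):
        X = rng.standard_normal((20, 6))
        y = rng.standard_normal(20)
        sel = lasso_select(X, y, lam=1e6)
        assert sel.selected.size == 0
        np.testing.assert_array_equal(sel.beta, 0.0)

    def test_tiny_lambda_keeps_linear_driver(self, rng):
        X = rng.standard_normal((50, 4))
        y = X[:, 0].copy()
        sel = lasso_select(X, y, lam=1e-4)
        assert 0 in sel.selected

    def test_nonpositive_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            lasso_select(rng.standard_normal((10, 3)), np.zeros(10), lam=0.0)


class TestSparseSpatialFilter:
    def test_selection_indexing_and_provenance(self, rng):
        be = _band_epochs(rng, n_bands=2)
        stack = band_filter_stack(be, m=4)   # 16 columns per band
        from mieeg.cspselect import LassoSelection
        beta = np.zeros(32)
        beta[[0, 17]] = 1.0
        sel = LassoSelection(beta=beta, beta0=0.0, lam=0.1,
                             selected=np.array([0, 17]))
        W = sparse_spatial_filter(sel, stack)
        assert W.n_sel == 2
        np.testing.assert_array_equal(W.band_of_column, [0, 1])
        np.testing.assert_allclose(W.W, stack.columns()[:, [0, 17]])

    def test_all_selected_equals_full_stack(self, rng):
        be = _band_epochs(rng, n_bands=1)
        stack = band_filter_stack(be, m=2)
        from mieeg.cspselect import LassoSelection
        n = stack.n_columns
        sel = LassoSelection(beta=np.ones(n), beta0=0.0, lam=0.1,
                             selected=np.arange(n))
        W = sparse_spatial_filter(sel, stack)
        np.testing.assert_allclose(W.W, stack.columns())

    def test_empty_selection_advises_smaller_lambda(self, rng):
        be = _band_epochs(rng, n_bands=1)
        stack = band_filter_stack(be, m=2)
        from mieeg.cspselect import LassoSelection
        sel = LassoSelection(beta=np.zeros(8), beta0=0.0, lam=9.0,
                             selected=np.array([], dtype=int))
        with pytest.raises(ValueError, match="lambda"):
            sparse_spatial_filter(sel, stack)


class TestApplySparseFilter:
    def _filter(self, C=4):
        from mieeg.cspselect import SparseSpatialFilter
        return SparseSpatialFilter(W=np.eye(C)[:, :2],
                                   provenance=[(0, 1, 0), (0, 1, 1)],
                                   band_of_column=np.zeros(2, dtype=int))

    def test_identity_columns_pick_channels(self, rng):
        x = rng.standard_normal((1, 4, 50))
        Z = apply_sparse_filter(x, self._filter())
        np.testing.assert_allclose(Z, x[0, :2])

    def test_output_shape(self, rng):
        from mieeg.cspselect import SparseSpatialFilter
        W = SparseSpatialFilter(W=rng.standard_normal((22, 16)),
                                provenance=[(0, 1, k) for k in range(16)],
                                band_of_column=np.zeros(16, dtype=int))
        Z = apply_sparse_filter(rng.standard_normal((1, 22, 1000)), W)
        assert Z.shape == (16, 1000)

    def test_linearity(self, rng):
        x = rng.standard_normal((2, 4, 30))
        f = self._filter()
        np.testing.assert_allclose(apply_sparse_filter(2 * x, f),
                                   2 * apply_sparse_filter(x, f))

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="channel"):
            apply_sparse_filter(rng.standard_normal((1, 6, 30)), self._filter(4))


class TestSelectorOnSyntheticData:
    def test_informative_band_dominates_selection(self):
        # all 4 classes carry their power in 8-12 Hz (band index 2)
        cfg = SynthConfig(n_subjects=1, trials_per_class=15, C=8, fs=64.0,
                          T_seconds=2.0, snr=2.5, subject_shift_sd=0.0,
                          class_bands={c: (8.0, 12.0) for c in (1, 2, 3, 4)},
                          seed=21)
        ds = make_dataset(cfg)[0]
        bands = ((1, 4), (4, 8), (8, 12), (12, 16), (16, 20), (20, 24), (24, 28))
        sel = SparseCSPSelector(m=2, lam=0.05, fs=64.0, bands=bands, seed=0)
        sel.fit(ds.data, ds.labels)
        from_informative = (sel.sparse_filter_.band_of_column == 2).mean()
        assert from_informative >= 0.5

    def test_transform_returns_selected_columns(self, small_dataset):
        bands = ((4, 8), (8, 12), (16, 20), (20, 24))
        sel = SparseCSPSelector(m=2, lam=0.05, fs=64.0, bands=bands, seed=0)
        sel.fit(small_dataset.data, small_dataset.labels)
        F = sel.transform(small_dataset.data[:5])
        assert F.shape == (5, sel.sparse_filter_.n_sel)
        P = sel.project(small_dataset.data[:2])
        assert P.shape == (2, sel.sparse_filter_.n_sel, small_dataset.n_samples)
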