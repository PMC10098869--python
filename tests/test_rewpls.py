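"""Covariance recursion, kernel-PLS fitting and knee-point selection."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.cross_decomposition import PLSRegression

from trajdec import rewpls

from .oracles import nipals_pls


def _random_data(rng, n=200, d=20, m=6, rank=None):
    if rank is None:
        x = rng.standard_normal((n, d))
    else:
        x = rng.standard_normal((n, rank)) @ rng.standard_normal((rank, d))
    coef = rng.standard_normal((d, m))
    y = x @ coef + 0.1 * rng.standard_normal((n, m))
    return x, y


class TestCovarianceRecursion:
    def test_lambda_one_equals_single_batch(self, rng):
        x, y = _random_data(rng)
        full = rewpls.CovarianceState.initial(20, 6)
        rewpls.update_covariances(full, x.T, y.T)
        split = rewpls.CovarianceState.initial(20, 6)
        rewpls.update_covariances(split, x[:70].T, y[:70].T)
        rewpls.update_covariances(split, x[70:].T, y[70:].T)
        np.testing.assert_allclose(split.cyy, full.cyy, rtol=1e-12)
        np.testing.assert_allclose(split.cyz, full.cyz, rtol=1e-12)
        np.testing.assert_allclose(split.weight, full.weight)

    def test_lambda_zero_keeps_latest_batch(self, rng):
        x, y = _random_data(rng, n=50)
        state = rewpls.CovarianceState.initial(20, 6, lam=1.0)
        rewpls.update_covariances(state, x[:25].T, y[:25].T)
        rewpls.update_covariances(state, x[25:].T, y[25:].T, lam=0.0)
        np.testing.assert_allclose(state.cyy, x[25:].T @ x[25:], rtol=1e-12)
        np.testing.assert_allclose(state.cyz, x[25:].T @ y[25:], rtol=1e-12)

    def test_hand_unrolled_recursion(self):
        y1 = np.array([[1.0], [2.0]])
        y2 = np.array([[3.0], [-1.0]])
        z1 = np.array([[2.0]])
        z2 = np.array([[0.5]])
        state = rewpls.CovarianceState.initial(2, 1, lam=0.5)
        rewpls.update_covariances(state, y1, z1)
        rewpls.update_covariances(state, y2, z2)
        expected_cyy = 0.5 * (y1 @ y1.T) + y2 @ y2.T
        expected_cyz = 0.5 * (y1 @ z1.T) + y2 @ z2.T
        np.testing.assert_allclose(state.cyy, expected_cyy, rtol=1e-14)
        np.testing.assert_allclose(state.cyz, expected_cyz, rtol=1e-14)

    def test_dimension_change_rejected(self, rng):
        state = rewpls.CovarianceState.initial(4, 2)
        rewpls.update_covariances(state, rng.standard_normal((4, 10)), rng.standard_normal((2, 10)))
        with pytest.raises(ValueError):
            rewpls.update_covariances(state, rng.standard_normal((5, 10)), rng.standard_normal((2, 10)))

    @given(st.integers(0, 2**31 - 1), st.integers(2, 5))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_batch_order_invariance_at_lambda_one(self, seed, n_parts):
        rng = np.random.default_rng(seed)
        x, y = _random_data(rng, n=60, d=6, m=2)
        ref = rewpls.CovarianceState.initial(6, 2)
        rewpls.update_covariances(ref, x.T, y.T)
        cuts = np.sort(rng.choice(np.arange(1, 60), n_parts - 1, replace=False))
        state = rewpls.CovarianceState.initial(6, 2)
        for part_x, part_y in zip(np.split(x, cuts), np.split(y, cuts)):
            if len(part_x):
                rewpls.update_covariances(state, part_x.T, part_y.T)
        np.testing.assert_allclose(state.cyy, ref.cyy, rtol=1e-10)
        np.testing.assert_allclose(state.cyz, ref.cyz, rtol=1e-10)


class TestFitFromCovariances:
    def test_matches_direct_batch_pls(self, rng):
        # the covariance-recursion fit at lam=1 must coincide with a direct
        # batch PLS on the raw centered data (independent NIPALS oracle)
        x, y = _random_data(rng, n=200, d=20, m=6)
        state = rewpls.CovarianceState.initial(20, 6)
        rewpls.update_covariances(state, x.T, y.T)
        model = rewpls.fit_from_covariances(state, 5)
        coef_oracle, *_ = nipals_pls(x, y, 5)
        assert np.max(np.abs(model.coef - coef_oracle)) < 1e-8

    def test_matches_sklearn_cross_check(self, rng):
        x, y = _random_data(rng, n=150, d=12, m=3)
        state = rewpls.CovarianceState.initial(12, 3)
        rewpls.update_covariances(state, x.T, y.T)
        model = rewpls.fit_from_covariances(state, 4)
        sk = PLSRegression(n_components=4, scale=False).fit(x, y)
        # sklearn's NIPALS stops at its own 1e-6 inner tolerance, so this
        # cross-check is necessarily looser than the high-precision oracle
        assert np.max(np.abs(model.coef - sk.coef_.T)) < 5e-3

    def test_full_rank_equals_ols(self, rng):
        x, y = _random_data(rng, n=300, d=15, m=4)
        state = rewpls.CovarianceState.initial(15, 4)
        rewpls.update_covariances(state, x.T, y.T)
        model = rewpls.fit_from_covariances(state, 15)
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        coef_ols = np.linalg.solve(xc.T @ xc, xc.T @ yc)
        assert np.max(np.abs(model.coef - coef_ols)) < 1e-6

    def test_single_response_first_direction(self, rng):
        # classical one-component PLS: w proportional to the centered
        # cross-covariance
        x, y = _random_data(rng, n=100, d=8, m=1)
        state = rewpls.CovarianceState.initial(8, 1)
        rewpls.update_covariances(state, x.T, y.T)
        model = rewpls.fit_from_covariances(state, 1)
        _, cyz, *_ = state.centered()
        w = model.weights[0]
        cos = abs(w @ cyz[:, 0]) / (np.linalg.norm(w) * np.linalg.norm(cyz))
        assert cos > 1 - 1e-12

    def test_rank_truncation_warns(self, rng):
        x, y = _random_data(rng, n=100, d=10, m=2, rank=3)
        y = x @ np.zeros((10, 2))  # zero response: nothing to extract after 0
        state = rewpls.CovarianceState.initial(10, 2)
        rewpls.update_covariances(state, x.T, (y + 1e-16).T)
        with pytest.raises(ValueError):
            rewpls.fit_from_covariances(state, 5)

    def test_memory_contract_streaming(self, rng):
        # the fit consumes only the fixed-size state: stream many batches and
        # fit without any retained raw data
        d, m = 10, 2
        state = rewpls.CovarianceState.initial(d, m)
        coef_true = rng.standard_normal((d, m))
        for _ in range(200):
            xb = rng.standard_normal((d, 500))
            zb = coef_true.T @ xb + 0.01 * rng.standard_normal((m, 500))
            rewpls.update_covariances(state, xb, zb)
        model = rewpls.fit_from_covariances(state, d)
        assert np.max(np.abs(model.coef - coef_true)) < 0.01


class TestPredict:
    def test_mean_input_gives_mean_prediction(self, rng):
        x, y = _random_data(rng, n=80, d=6, m=3)
        state = rewpls.CovarianceState.initial(6, 3)
        rewpls.update_covariances(state, x.T, y.T)
        model = rewpls.fit_from_covariances(state, 3)
        z_hat, scores = rewpls.predict(model, model.mean_y[:, None])
        np.testing.assert_allclose(z_hat[:, 0], model.mean_z, atol=1e-10)
        np.testing.assert_allclose(scores, 0.0, atol=1e-10)
        assert scores.shape[0] == model.n_components

    def test_exact_recovery_on_noiseless_linear_data(self, rng):
        rank = 4
        x = rng.standard_normal((300, rank)) @ rng.standard_normal((rank, 10))
        y = x @ rng.standard_normal((10, 3))
        state = rewpls.CovarianceState.initial(10, 3)
        rewpls.update_covariances(state, x.T, y.T)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = rewpls.fit_from_covariances(state, rank)
        z_hat, _ = rewpls.predict(model, x.T)
        err = np.abs(z_hat - y.T).max() / np.abs(y).max()
        assert err < 1e-8


class TestComponentSelection:
    def test_knee_finds_true_rank(self, rng):
        # 3 informative latent directions, weak noise: the CV curve rises to
        # a plateau at A=3 and the chord-distance knee must find it
        n, d = 600, 15
        latent = rng.standard_normal((n, 3))
        x = latent @ rng.standard_normal((3, d)) + 0.05 * rng.standard_normal((n, d))
        z = latent @ rng.standard_normal((3, 4)) + 0.05 * rng.standard_normal((n, 4))
        a_star, curve = rewpls.select_components(x.T, z.T, a_max=10)
        assert a_star == 3
        # brute-force knee over the computed curve agrees
        assert rewpls.knee_point(curve) == a_star

    def test_linear_curve_tie_breaks_to_one(self):
        assert rewpls.knee_point(np.linspace(0.1, 0.9, 8)) == 1

    def test_monotone_cv_on_noiseless_linear_data(self, rng):
        rank = 5
        x = rng.standard_normal((400, rank)) @ rng.standard_normal((rank, 12))
        z = x @ rng.standard_normal((12, 4))
        _, curve = rewpls.select_components(x.T, z.T, a_max=rank)
        assert np.all(np.diff(curve) > -1e-9)

    def test_folds_partition_samples(self):
        folds = rewpls._contiguous_folds(103, 10)
        all_idx = np.concatenate(folds)
        assert len(all_idx) == 103
        assert len(np.unique(all_idx)) == 103

    def test_degenerate_curve_warns_and_returns_one(self, rng):
        x = rng.standard_normal((100, 5))
        z = rng.standard_normal((100, 2)) * 0 + 1.0  # constant target
        with pytest.warns(RuntimeWarning):
            a_star, _ = rewpls.select_components(x.T, z.T, a_max=4, n_folds=5)
        assert a_star == 1
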