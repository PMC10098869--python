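"""Metrics, trial shuffling, chance thresholds and paired statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trajdec import evaluation


class TestExtendKinematics:
    def test_pythagorean_triple(self):
        z = np.array([[3.0], [0.0], [4.0], [0.0]])
        out = evaluation.extend_kinematics(z)
        assert out[4, 0] == 5.0
        assert out[5, 0] == 0.0

    def test_sqrt_two(self):
        z = np.array([[1.0], [1.0], [1.0], [1.0]])
        out = evaluation.extend_kinematics(z)
        np.testing.assert_allclose(out[4, 0], np.sqrt(2.0), rtol=1e-12)
        np.testing.assert_allclose(out[5, 0], np.sqrt(2.0), rtol=1e-12)

    def test_nonnegative(self, rng):
        z = rng.standard_normal((4, 100))
        out = evaluation.extend_kinematics(z)
        assert np.all(out[4] >= 0) and np.all(out[5] >= 0)


class TestPearson:
    def test_identity_and_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0])
        assert evaluation.pearson_r(x, x) == 1.0
        assert evaluation.pearson_r(x, x[::-1]) == -1.0

    def test_hand_computed_value(self):
        # manual arithmetic through the definition's sums
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        assert abs(evaluation.pearson_r(x, y) - 0.6) < 1e-12

    def test_symmetry(self, rng):
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        assert evaluation.pearson_r(x, y) == evaluation.pearson_r(y, x)

    def test_constant_input_nan_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out = evaluation.pearson_r(np.ones(5), np.arange(5.0))
        assert np.isnan(out)


class TestSnr:
    def test_mean_prediction_is_zero_db(self, rng):
        x = rng.standard_normal(200)
        y = np.full_like(x, x.mean())
        assert abs(evaluation.snr_db(x, y)) < 1e-12

    def test_noise_amplitude_times_ten_drops_20_db(self, rng):
        x = rng.standard_normal(5000)
        noise = rng.standard_normal(5000)
        a = evaluation.snr_db(x, x + 0.1 * noise)
        b = evaluation.snr_db(x, x + 1.0 * noise)
        np.testing.assert_allclose(a - b, 20.0, atol=1e-10)

    def test_perfect_reconstruction_inf(self, rng):
        x = rng.standard_normal(10)
        assert evaluation.snr_db(x, x.copy()) == np.inf

    def test_argument_order_matters(self):
        # deliberately asymmetric fixture: truth first
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 2.0, 30.0])
        assert evaluation.snr_db(x, y) != evaluation.snr_db(y, x)


class TestShuffling:
    def test_permutation_preserves_multiset(self, rng):
        z = rng.standard_normal((4, 60))
        trials = tuple((k * 15, (k + 1) * 15) for k in range(4))
        shuf = evaluation.shuffle_trials(z, trials, rng)
        segs = lambda m: sorted(tuple(m[:, a:b].ravel()) for a, b in trials)
        assert segs(shuf) == segs(z)

    def test_single_trial_rejected(self, rng):
        with pytest.raises(ValueError):
            evaluation.shuffle_trials(np.zeros((4, 10)), ((0, 10),), rng)

    def test_unequal_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            evaluation.shuffle_trials(np.zeros((4, 10)), ((0, 4), (4, 10)), rng)


class TestChance:
    def test_full_scale_plan(self):
        from trajdec.scenarios import enumerate_unique_models

        plan = evaluation.chance_plan(10, enumerate_unique_models(3), 100)
        assert len(plan) == 9000

    def test_threshold_monotone_in_percentile(self, rng):
        dist = rng.uniform(size=(40, 2, 6))
        t90 = evaluation.chance_threshold(dist, 90)
        t95 = evaluation.chance_threshold(dist, 95)
        t99 = evaluation.chance_threshold(dist, 99)
        assert np.all(t90 <= t95) and np.all(t95 <= t99)

    def test_distribution_shape_and_range(self, rng):
        d = 12
        trials = tuple((k * 40, (k + 1) * 40) for k in range(4))
        y = rng.standard_normal((d, 160))
        z = rng.standard_normal((6, 160))
        dist = evaluation.chance_distribution(
            y, z, trials, [(y, z)], n_components=3, n_repeats=5, rng=rng
        )
        assert dist.shape == (5, 1, 6)
        assert np.all(dist >= 0) and np.all(dist <= 1)


class TestCompareStrategies:
    def test_exact_signed_rank_p_value(self):
        # exhaustive-enumeration oracle: all-positive differences of n=5
        # give one-sided p = 1/32, two-sided 1/16
        res = stats.wilcoxon(
            np.array([1.0, 2.0, 3.0, 4.0, 5.0]), alternative="two-sided"
        )
        assert abs(res.pvalue - 1.0 / 16.0) < 1e-12

    def test_bh_adjustment_hand_applied(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04], rtol=1e-12)

    def _table(self, rng, shift=0.0):
        rows = []
        for p in range(8):
            for session in (1, 2):
                for block in ("0", "50"):
                    for kin in ("p_hor", "p_ver", "v_hor", "v_ver", "d", "s"):
                        base = rng.uniform(0.1, 0.5)
                        for strat, delta in (("Gen", 0.0), ("Ind", shift)):
                            rows.append(
                                dict(
                                    participant=p, session=session, block=block,
                                    strategy=strat, space="sensor", kinematic=kin,
                                    r=base + delta + 0.01 * rng.standard_normal(),
                                    snr=-5.0 + 10 * (base + delta),
                                )
                            )
        return pd.DataFrame(rows)

    def test_detects_shift_and_orders_pvalues(self, rng):
        table = self._table(rng, shift=0.2)
        out = evaluation.compare_strategies(table)
        assert set(out["group"]) == {"position", "velocity", "nonlinear"}
        assert (out["p_fdr"] >= out["p_raw"] - 1e-15).all()
        assert (out["p_raw"] < 0.01).all()

    def test_identical_distributions_degenerate(self, rng):
        # literally identical paired values: every difference is zero, the
        # signed-rank test is degenerate and reported as NaN, never as a
        # spurious rejection
        table = self._table(rng, shift=0.0)
        wide = table.copy()
        ind = wide[wide["strategy"] == "Gen"].copy()
        ind["strategy"] = "Ind"
        out = evaluation.compare_strategies(
            pd.concat([wide[wide["strategy"] == "Gen"], ind], ignore_index=True)
        )
        assert out["p_raw"].isna().all()
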