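"""LOPO pooling, update strategies and model enumeration."""

import numpy as np
import pytest

from trajdec import evaluation, rewpls, scenarios, synthgen
from trajdec.scenarios import DecoderConfig, StudyFeatures


@pytest.fixture(scope="module")
def cfg():
    return DecoderConfig(a_max=8, n_folds=5)


@pytest.fixture(scope="module")
def study3():
    design = synthgen.StudyDesign(
        n_participants=3, n_sessions=3, n_trials_per_block=2,
        trial_duration_s=10.0, n_channels=16, n_locations=84,
    )
    return synthgen.gen_study(design, "shared", snr_db=10.0, seed=41)


@pytest.fixture(scope="module")
def feats3(study3, cfg):
    return StudyFeatures(study3, space="sensor", cfg=cfg)


class TestEnumeration:
    def test_default_design_nine_models(self):
        names = scenarios.enumerate_unique_models(3)
        assert len(names) == 9
        assert set(names) == {
            "Gen", "GenC1", "GenC2", "GenC3",
            "Ind1", "Ind2", "Ind3", "IndC2", "IndC3",
        }

    def test_single_session_collapses_to_three(self):
        # brute-force enumeration of the merge rules: with one session only
        # Gen, GenC1 and Ind1 exist (IndC1 aliases Ind1)
        assert scenarios.enumerate_unique_models(1) == ["Gen", "GenC1", "Ind1"]

    def test_no_duplicates(self):
        for s in (1, 2, 3, 5):
            names = scenarios.enumerate_unique_models(s)
            assert len(names) == len(set(names))


class TestLopo:
    def test_training_pool_composition(self, study3, feats3, cfg):
        model = scenarios.train_lopo(study3, 1, feats3, cfg)
        assert set(model.training_blocks) == {(0, 1, "0"), (2, 1, "0")}

    def test_unknown_participant_rejected(self, study3, feats3, cfg):
        with pytest.raises(ValueError):
            scenarios.train_lopo(study3, 7, feats3, cfg)

    def test_lopo_models_differ_when_couplings_differ(self, cfg):
        design = synthgen.StudyDesign(
            n_participants=3, n_sessions=1, n_trials_per_block=2,
            trial_duration_s=10.0, n_channels=16, n_locations=84,
        )
        study = synthgen.gen_study(design, "participant_specific", snr_db=10.0, seed=42)
        feats = StudyFeatures(study, space="sensor", cfg=cfg)
        m0 = scenarios.train_lopo(study, 0, feats, cfg)
        m1 = scenarios.train_lopo(study, 1, feats, cfg)
        assert not np.allclose(m0.pls.coef, m1.pls.coef)

    def test_lopo_transfer_beats_chance_with_shared_coupling(self, study3, feats3, cfg):
        # positive control for transfer: held-out velocity correlation above
        # the trial-shuffled chance threshold
        model = scenarios.train_lopo(study3, 2, feats3, cfg)
        y, z, trials = feats3.block(2, 1, "0")
        z_hat = model.decode(y)
        r_v = abs(evaluation.pearson_r(z[1], z_hat[1]))
        y_tr = np.hstack([feats3.block(*k)[0] for k in model.training_blocks])
        z_tr = np.hstack([feats3.block(*k)[1] for k in model.training_blocks])
        tr_trials = []
        off = 0
        for k in model.training_blocks:
            for a, b in feats3.block(*k)[2]:
                tr_trials.append((a + off, b + off))
            off = tr_trials[-1][1]
        dist = evaluation.chance_distribution(
            y_tr, z_tr, tuple(tr_trials), [(y, z)],
            n_components=model.n_components, n_repeats=10,
            rng=np.random.default_rng(7),
        )
        thr = evaluation.chance_threshold(dist)
        assert r_v > thr[1]


class TestRunStrategy:
    def test_gen_model_identical_everywhere(self, study3, feats3, cfg):
        decoded, registry = scenarios.run_strategy(study3, 0, "Gen", feats3, cfg)
        assert list(registry) == ["Gen"]
        assert len(decoded) == 9

    def test_indc1_equals_ind1(self, study3, feats3, cfg):
        _, reg_ind = scenarios.run_strategy(study3, 0, "Ind", feats3, cfg)
        _, reg_indc = scenarios.run_strategy(study3, 0, "IndC", feats3, cfg)
        np.testing.assert_array_equal(
            reg_ind["Ind1"].pls.coef, reg_indc["Ind1"].pls.coef
        )

    def test_indc_state_equals_concatenation_oracle(self, study3, feats3, cfg):
        _, registry = scenarios.run_strategy(study3, 0, "IndC", feats3, cfg)
        model = registry["IndC2"]
        assert set(model.training_blocks) == {(0, 1, "0"), (0, 2, "0")}
        y = np.hstack([feats3.block(*k)[0] for k in sorted(model.training_blocks)])
        z = np.hstack([feats3.block(*k)[1] for k in sorted(model.training_blocks)])
        single = rewpls.CovarianceState.initial(y.shape[0], z.shape[0])
        rewpls.update_covariances(single, y, z)
        np.testing.assert_allclose(model.state.cyy, single.cyy, rtol=1e-10)
        np.testing.assert_allclose(model.state.cyz, single.cyz, rtol=1e-10)

    def test_causality_no_model_trained_on_its_own_or_later_blocks(self, study3, feats3, cfg):
        block_order = {
            (s, b): i
            for i, (s, b) in enumerate(
                (s, b) for s in (1, 2, 3) for b in ("0", "50", "100")
            )
        }
        for strategy in scenarios.STRATEGIES:
            decoded, registry = scenarios.run_strategy(study3, 0, strategy, feats3, cfg)
            # rebuild which model decoded which block and check its pool
            current = "Gen"
            for (s, b) in sorted(block_order, key=block_order.get):
                model = registry[current] if current in registry else registry["Gen"]
                for (tp, ts, tb) in model.training_blocks:
                    if tp != 0:
                        continue  # other participants' data: session-1 pool
                    assert block_order[(ts, tb)] < block_order[(s, b)]
                if b == "0" and strategy != "Gen":
                    session_name = {
                        "GenC": f"GenC{s}", "Ind": f"Ind{s}",
                        "IndC": f"Ind{s}" if s == 1 else f"IndC{s}",
                    }[strategy]
                    current = session_name

    def test_unknown_strategy_rejected(self, study3, feats3, cfg):
        with pytest.raises(ValueError):
            scenarios.run_strategy(study3, 0, "Foo", feats3, cfg)

    def test_genc_pool_grows_with_sessions(self, study3, feats3, cfg):
        _, registry = scenarios.run_strategy(study3, 0, "GenC", feats3, cfg)
        lopo_pool = set(registry["Gen"].training_blocks)
        g1 = set(registry["GenC1"].training_blocks)
        g2 = set(registry["GenC2"].training_blocks)
        assert g1 == lopo_pool | {(0, 1, "0")}
        assert g2 == g1 | {(0, 2, "0")}


def test_source_space_features_have_expected_dimension(study3, cfg):
    feats = StudyFeatures(study3, space="source", cfg=cfg)
    y, z, trials = feats.block(0, 1, "0")
    assert y.shape[0] == 588  # 84 scouted source features x 7 lags
    assert z.shape[0] == 6
    assert y.shape[1] == z.shape[1]
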