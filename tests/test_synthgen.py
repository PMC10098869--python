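"""Generator contracts: geometry, snake spectra, coupling and reproducibility."""

import numpy as np
import pytest
from scipy import signal

from trajdec import evaluation, preprocess, synthgen
from trajdec.containers import ROI_LABELS


class TestLeadfield:
    def test_full_scale_dimensions(self):
        lf = synthgen.gen_leadfield(60, 5000, seed=0)
        assert lf.gain.shape == (60, 15000)
        assert len(set(lf.roi_map)) == 28

    def test_roi_partition_complete(self, small_leadfield):
        labels = set(small_leadfield.roi_map)
        assert labels == set(ROI_LABELS)

    def test_single_source_sensor_vector_is_gain_column(self, small_leadfield):
        lf = small_leadfield
        q = 3 * 7 + 1  # arbitrary orientation component
        j = np.zeros((lf.n_components, 1))
        j[q] = 1.0
        x = lf.gain @ j
        assert np.array_equal(x[:, 0], lf.gain[:, q])

    def test_strongest_electrode_is_nearest(self, small_leadfield):
        # brute-force oracle: per location, the electrode with the largest
        # gain magnitude (norm over the 3 orientation columns) must be among
        # the 5 nearest electrodes by euclidean distance
        lf = small_leadfield
        for loc in range(lf.n_locations):
            block = lf.gain[:, 3 * loc : 3 * loc + 3]
            strongest = np.argmax(np.linalg.norm(block, axis=1))
            dists = np.linalg.norm(
                lf.electrode_positions - lf.source_positions[loc], axis=1
            )
            assert strongest in np.argsort(dists)[:5]

    def test_rejects_too_few_locations(self):
        with pytest.raises(ValueError):
            synthgen.gen_leadfield(16, 27, seed=0)


class TestSnake:
    def test_sample_count(self):
        kin = synthgen.gen_snake(60, 20, seed=0)
        assert kin.pos.shape == (2, 1200)
        assert kin.vel.shape == (2, 1200)

    def test_velocity_is_position_derivative(self):
        # high-order central differences converge to the analytic derivative
        kin = synthgen.gen_snake(30, 200, band_hz=(0.1, 1.5), seed=3)
        coeffs = np.array([3, -32, 168, -672, 0, 672, -168, 32, -3]) / 840.0
        for dim in range(2):
            num = np.convolve(kin.pos[dim], coeffs[::-1], mode="valid") * kin.fs
            ana = kin.vel[dim][4:-4]
            scale = np.abs(kin.vel[dim]).max()
            assert np.max(np.abs(num - ana)) < 1e-6 * scale

    def test_spectral_power_inside_band(self):
        band = (0.2, 1.0)
        kin = synthgen.gen_snake(120, 20, band_hz=band, seed=4)
        f, pxx = signal.periodogram(kin.pos[0], fs=20)
        inside = (f >= band[0] - 0.05) & (f <= band[1] + 0.05)
        assert pxx[inside].sum() / pxx.sum() >= 0.99

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            synthgen.gen_snake(-5, 20)
        with pytest.raises(ValueError):
            synthgen.gen_snake(10, 20, band_hz=(0.5, 11.0))


class TestStudy:
    def test_shared_coupling_identical(self, tiny_study):
        b0 = tiny_study.coupling[(0, 1)]
        for key, b in tiny_study.coupling.items():
            assert np.array_equal(b, b0)

    def test_participant_specific_coupling_differs(self, tiny_design):
        study = synthgen.gen_study(tiny_design, "participant_specific", seed=5)
        assert not np.allclose(study.coupling[(0, 1)], study.coupling[(1, 1)])
        # but constant across sessions of one participant
        assert np.array_equal(study.coupling[(0, 1)], study.coupling[(0, 2)])

    def test_session_drift_rotates_coupling(self, tiny_design):
        study = synthgen.gen_study(tiny_design, "session_drift", seed=5)
        b1, b2 = study.coupling[(0, 1)], study.coupling[(0, 2)]
        assert not np.allclose(b1, b2)
        # a rotation preserves row norms
        np.testing.assert_allclose(
            np.linalg.norm(b1, axis=1), np.linalg.norm(b2, axis=1), rtol=1e-10
        )

    def test_unknown_mode_rejected(self, tiny_design):
        with pytest.raises(ValueError):
            synthgen.gen_study(tiny_design, "bogus")

    def test_noiseless_single_location_exact_mixture(self):
        # one coupled location, no background, no sensor noise: every sensor
        # row is an exact linear mixture of the lagged kinematic drive
        design = synthgen.StudyDesign(
            n_participants=1, n_sessions=1, n_trials_per_block=2,
            trial_duration_s=5.0, n_channels=8, n_locations=28,
            coupling_rois=synthgen.ROI_BASE_NAMES,  # every ROI couples
            background_rms=0.0,
        )
        study = synthgen.gen_study(design, "shared", snr_db=np.inf, seed=7)
        rec = study.recordings[(0, 1, "0")]
        kin = study.kinematics[(0, 1, "0")]
        drive = synthgen._lagged_drive(kin, design.coupling_lags)
        x = rec.data.astype(float)
        # rank of X cannot exceed rank of the drive
        rank_drive = np.linalg.matrix_rank(drive)
        assert np.linalg.matrix_rank(x, tol=1e-6 * np.abs(x).max()) <= rank_drive
        # each sensor row is reproduced exactly by regression on the drive
        coef, *_ = np.linalg.lstsq(drive.T, x.T, rcond=None)
        resid = x.T - drive.T @ coef
        assert np.max(np.abs(resid)) < 1e-4 * np.abs(x).max()

    def test_sensor_noise_power_matches_snr(self, tiny_design):
        snr_db = 6.0
        clean = synthgen.gen_study(tiny_design, "shared", snr_db=np.inf, seed=9)
        noisy = synthgen.gen_study(tiny_design, "shared", snr_db=snr_db, seed=9)
        key = (0, 1, "0")
        sig = clean.recordings[key].data.astype(float)
        noise = noisy.recordings[key].data.astype(float) - sig
        measured = 10 * np.log10(np.mean(sig**2) / np.mean(noise**2))
        assert abs(measured - snr_db) < 0.5

    def test_bit_identical_regeneration(self, tiny_design):
        a = synthgen.gen_study(tiny_design, "shared", snr_db=10, seed=33)
        b = synthgen.gen_study(tiny_design, "shared", snr_db=10, seed=33)
        key = (1, 2, "50")
        assert np.array_equal(a.recordings[key].data, b.recordings[key].data)
        assert np.array_equal(a.kinematics[key].pos, b.kinematics[key].pos)

    def test_total_sample_count(self, tiny_study):
        d = tiny_study.design
        total = sum(rec.n_samples for rec in tiny_study.recordings.values())
        expected = (
            d.samples_per_block * len(d.blocks) * d.n_sessions * d.n_participants
        )
        assert total == expected

    def test_shared_coupling_transfers_with_ols(self, tiny_study):
        # positive control: with shared coupling an ordinary least-squares
        # decoder fitted on participant 0 transfers to participant 1
        def feats(p):
            rec = tiny_study.recordings[(p, 1, "0")]
            kin = tiny_study.kinematics[(p, 1, "0")]
            proc = preprocess.common_average_reference(preprocess.filter_chain(rec))
            lag = preprocess.lag_expand(proc.data, proc.trials)
            kin20 = preprocess.resample_kinematics(kin, 20)
            z = kin20.as_matrix()[:, lag.kept_columns]
            return lag.data, z

        y0, z0 = feats(0)
        y1, z1 = feats(1)
        # normal-equations ridge-free OLS oracle
        x0 = np.vstack([y0, np.ones(y0.shape[1])])
        coef = np.linalg.lstsq(x0.T, z0.T, rcond=None)[0]
        pred = coef.T @ np.vstack([y1, np.ones(y1.shape[1])])
        r_vhor = evaluation.pearson_r(z1[1], pred[1])
        r_vver = evaluation.pearson_r(z1[3], pred[3])
        assert min(r_vhor, r_vver) > 0.8
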