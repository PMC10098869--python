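"""Condition a recording and extract sensor- and source-space features.

Shows the full feature chain: 0.18 Hz high-pass, resampling to 20 Hz, common
average reference, sLORETA + ROI scouting (source space) and lag expansion,
with the kinematics kept sample-aligned throughout.
"""

from trajdec import preprocess, sourcespace, synthgen

design = synthgen.StudyDesign(
    n_participants=1, n_sessions=1, n_trials_per_block=2,
    trial_duration_s=10.0, n_channels=16, n_locations=84,
)
study = synthgen.gen_study(design, "shared", snr_db=10.0, seed=2)
rec = study.recordings[(0, 1, "0")]
print(f"raw recording      : {rec.data.shape} at {rec.fs:.0f} Hz")

proc = preprocess.common_average_reference(preprocess.filter_chain(rec))
print(f"after conditioning : {proc.data.shape} at {proc.fs:.0f} Hz "
      f"(column means ~ {abs(proc.data.mean(axis=0)).max():.1e} after CAR)")

# sensor-space features: channels x lags
lagged = preprocess.lag_expand(proc.data, proc.trials)
print(f"sensor features    : {lagged.data.shape[0]} rows "
      f"({proc.n_channels} channels x {lagged.n_lags} lags, "
      f"lags {preprocess.lag_times_ms()} ms)")

# source-space features: sLORETA -> 28 ROIs x 3 orientations -> lags
noise = preprocess.common_average_reference(
    preprocess.filter_chain(study.noise_blocks[0])
)
cov = sourcespace.estimate_noise_covariance(noise.data)
kernel = sourcespace.sloreta_kernel(study.leadfield, cov)
scout = sourcespace.build_scouting_matrix(study.leadfield)
feats = sourcespace.project_features(proc.data, kernel, scout)
src_lagged = preprocess.lag_expand(feats, proc.trials)
print(f"source features    : {feats.shape[0]} scouted signals "
      f"(28 ROIs x 3 orientation components) -> "
      f"{src_lagged.data.shape[0]} rows after lag expansion")

kin = preprocess.resample_kinematics(study.kinematics[(0, 1, '0')], 20.0)
print(f"aligned kinematics : {kin.as_matrix()[:, src_lagged.kept_columns].shape} "
      "(p_hor, v_hor, p_ver, v_ver)")
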