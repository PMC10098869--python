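# Methods

`trajdec` implements an offline simulated-online analysis of continuous 2-D
hand-trajectory decoding from low-frequency multichannel EEG-like signals:
synthetic study generation with known ground truth, signal conditioning,
source-space feature extraction, a recursive exponentially weighted PLS
decoder cascaded with a square-root unscented Kalman filter, four
model-update (transfer-learning) strategies over a multi-participant,
multi-session design, chance-level and statistical evaluation, and
forward-model decoding-pattern analysis.

## The generative model and the synthetic study

Sensor data follow the linear mixing model

    X = G J + n,

with `X` the (P x T) sensor series, `G` the (P x Q) gain (lead field), `J`
the (Q x T) source activity and `n` additive sensor noise.  The synthetic
generator (`synthgen`) instantiates every term:

* **Geometry / lead field.**  Electrodes sit on the upper surface of a unit
  sphere; `Q/3` source locations are spread over a concentric sphere of
  radius 0.85, each with three free orientation components.  The gain of an
  orientation component is `o . d / r^2` — a dipole-like kernel with a
  smooth distance falloff.  This is deliberately *not* a boundary-element
  head model: it reproduces the structural properties the pipeline depends
  on (smooth spatial mixing, distance-dependent attenuation, 3-component
  free orientation) without anatomical data.  The 28 regions of interest
  (cuneus, paracentral lobule, and the split superior frontal,
  pre-/postcentral, superior parietal, precuneus and occipital gyri, both
  hemispheres) are realized as contiguous angular patches via
  nearest-patch-center assignment.
* **Kinematics.**  The pursuit target ("snake") is a band-limited
  random trajectory: per dimension a sum of 24 random-phase sinusoids with
  frequencies uniform in 0.1–1.5 Hz; the velocity is the exact analytic
  derivative.  Blocks consist of contiguous fixed-length trials (default
  6 x 20 s = 120 s per block; trial length is a design choice — tiling the
  block exactly avoids partial trials).
* **Coupling.**  Sources inside designated coupling ROIs (default PCL,
  aPCU, pPCU, CU — the regions reported as informative for this task) carry
  `B zlag`, a fixed linear read-out of the lagged standardized kinematics
  (lags 0/50/100 ms); all other sources carry independent 1/f Gaussian
  background activity (RMS 0.5 relative to the unit-variance coupled
  sources).  `coupling_mode` decides whether `B` is identical across
  participants (`shared`), drawn independently per participant
  (`participant_specific`), or rotated in kinematic space per session
  (`session_drift`).  This knob is what makes transfer learning testable:
  shared coupling is the world in which across-participant transfer *can*
  work, participant-specific coupling the world in which it cannot.
* **Noise.**  White sensor noise is added at a configurable SNR (default
  10 dB against the noiseless sensor signal).

What the generator does **not** emulate: volume-conduction anatomy,
eye/muscle artifacts, non-stationarity within a session, feedback-dependent
behavior of the participant.  Passing tests therefore demonstrate the
correctness and calibration of the *analysis*, not decoding performance on
real EEG.

## Signal conditioning and features

The chain (`preprocess`) is: zero-phase 4th-order Butterworth high-pass at
0.18 Hz -> polyphase resampling to 100 Hz -> zero-phase 4th-order low-pass
at 3 Hz -> resampling to 20 Hz -> common average reference, followed by lag
expansion with lags 0 to -6 samples (0 to -300 ms).  Zero-phase filtering
keeps features and kinematics sample-aligned; the lag embedding is per
trial (the first 6 samples of each trial are dropped, never padded), so no
feature mixes data across a trial boundary.  Kinematics are decimated to
20 Hz by exact sub-sampling (they are band-limited far below the target
Nyquist rate) and extended with distance `d = sqrt(p_hor^2 + p_ver^2)` and
speed `s = sqrt(v_hor^2 + v_ver^2)`.

Sensor-space features are the conditioned channels (32 x 7 lags = 224 rows
at desk scale; 60 x 7 = 420 at full scale).  Source-space features apply
the inverse kernel and ROI scouting first: 28 ROIs x 3 orientation
components = 84 representative signals, hence 588 rows after lag expansion.

## Source imaging

`sourcespace` builds a standardized minimum-norm (sLORETA-style) kernel:
`T_MN = G'(G G' + alpha C)^-1` with noise covariance `C` estimated from a
noise-only block (diagonal loading 0.01 trace/P), standardized per location
by the symmetric inverse square root of the 3x3 resolution block
`(T_MN G)_ll`.  The regularization default is `alpha = 0.1 trace(G G') /
trace(C)`, a standard SNR-style heuristic; the sensor Gram matrix is
inverted through an eigendecomposition with a relative cutoff so that
common-average-referenced (rank P-1) lead fields are handled without
special-casing.  The estimator's zero-localization-error property in the
noiseless, weakly regularized limit is asserted by an exhaustive scan test.
ROI scouting averages sources within each ROI per orientation component
(rows sum to one, weights `1/R_i`).

## The decoder

### Recursive exponentially weighted PLS

The decoder's first stage is a PLS regression fit from recursively updated
non-normalized covariance matrices,

    (Y Y')_t = lam (Y Y')_t-1 + Y_b Y_b',
    (Y Z')_t = lam (Y Z')_t-1 + Y_b Z_b',

with the forgetting factor `lam = 1` throughout this analysis (equal weight
for all batches), so the state equals the inner products of the pooled data
and the fit is exactly a batch PLS — while memory stays independent of the
pool size.  The state also tracks exponentially weighted sums of features
and targets; covariances are centered at fit time, which is what makes the
`lam = 1` path agree with batch PLS on centered data to machine precision
(asserted against an independent NIPALS implementation at 1e-8, and against
ordinary least squares at full rank at 1e-6).  Fitting uses the modified
kernel algorithm #2 (per component: dominant left singular vector of the
current cross-covariance, orthogonalization against previous loadings,
deflation of the cross-covariance only).  If the requested component count
exceeds the informative rank the model truncates with a warning.

The component count is selected per fit by 10-fold cross-validation: the
curve of mean Pearson correlation of the four linear kinematics vs
`A = 1..A_max` (default 50), with the knee taken as the point of maximal
perpendicular distance to the chord joining the curve endpoints; ties and
degenerate straight curves resolve to the smallest `A`.

### Square-root UKF cascade

The PLS latent scores `E = W Y` pair with the extended kinematics `Z` to
train the second stage.  The state is the 6-dimensional extended
kinematics; the non-linear components d and s are what motivate a
sigma-point filter.  Both models are learned from data: a first-order
autoregressive transition `z_t = F z_t-1 + c + w` and a linear observation
`e_t = H z_t + b + v`, each by least squares with a ridge fallback for
rank-deficient regressors, with noise covariances from the residuals
(diagonal loading keeps them positive definite).

The process-noise covariance is inflated by `q_scale` (default 10).  The
latent noise in `E` is band-limited — the features were low-passed at 3 Hz
— while the filter assumes white measurement noise; with raw residual
covariances the filter over-smooths and introduces phase lag, *degrading*
the velocity correlation of the raw PLS output by ~0.03 on clean synthetic
data and much more on noisy data.  With the default inflation the cascade
preserves the raw decoder's correlation on clean data and improves it on
noisy data (and it is what makes d and s decodable at all, since the linear
PLS stage cannot represent them).

The filter maintains a lower-triangular Cholesky factor `S` of the state
covariance (`P = S S'`, never formed).  Sigma-point parameters default to
`alpha_s = 1e-3`, `beta_s = 2`, `kappa_s = 0`.  Factor updates with
negative weight (the 0-th sigma-point term) and the multi-column
measurement downdate are computed by whitening the update columns against
the current factor, taking a 6x6 Cholesky of `I + w V V'`, and
re-triangularizing by QR — algebraically the classic sequence of scalar
rank-1 `cholupdate`s, in three dense 6x6 operations.  A downdate that loses
positive definiteness falls back to an eigenvalue-clamped re-factorization
with a warning.  On a linear-Gaussian system the filter matches a
conventional full-covariance Kalman filter to ~1e-9 over 2000 steps.
Filtered d and s are recomputed from the filtered positions and velocities
so the output is internally consistent.

## Transfer-learning scenarios

For each participant, a leave-one-participant-out (LOPO) generalized model
is trained on the pooled session-1 calibration (0% feedback) blocks of all
other participants (`lam = 1`, one covariance batch per block).  Four update
strategies then run over the participant's sessions:

| strategy | update rule |
|---|---|
| Gen  | LOPO model applied everywhere, never updated |
| GenC | covariance state (LOPO pool + own prior 0% blocks) cumulatively extended after each session's 0% block; refit -> GenC1..3 |
| Ind  | fresh model from the current session's 0% block only -> Ind1..3 |
| IndC | state accumulates own 0% blocks of sessions 1..s -> IndC2..3 (IndC1 = Ind1) |

Every 0% block is decoded with the model carried in from *before* that
block, and updates happen only at the end of 0% blocks, so no block is ever
decoded by a model that saw it or any later block (asserted as a causality
test).  A 3-session design yields 9 unique models; the component count is
re-selected at every refit, and both cascade stages are refit from the
cumulative pool whenever the PLS state changes.  The feedback percentages
(50%/100%) label evaluation blocks only — offline there is no feedback loop
to simulate.

## Evaluation

Metrics are Pearson's r and the decoding SNR
`10 log10(var(truth)/MSE(truth, decoded))`; variance and MSE both use 1/n
normalization, so predicting the truth's mean gives exactly 0 dB.
Group-level correlation distributions use absolute values of the
participant-level correlations, computed per measurement block.

**Chance levels.**  Chance decoders are retrained on trial-shuffled
feature–kinematics pairings: the assignment of equal-length kinematic trial
segments to feature trials is permuted (content preserved, pairing broken),
and the full PLS + SR-UKF cascade is refit, reusing the matched model's
component count.  The per-participant threshold is the 95th percentile of
the absolute chance correlations over repeats, using the conservative
`higher` order statistic: with `n` repeats the threshold is the
`ceil(0.95 n)`-th order statistic, which keeps the matched-model coverage
at `~0.95` under the null for both 100 repeats and the reduced counts used
in the test suite (a linearly interpolated percentile would undershoot
badly at small `n`).  The group threshold is the median across
participants.  Calibration is verified by Monte Carlo: with features
independent of the kinematics, the matched model falls below the threshold
in 95% +- 3% of replicates.

Two caveats are inherent to the procedure and worth knowing.  A uniformly
random permutation of `k` trials has one fixed point on average, so with
few trials a fraction ~1/k of the shuffled training data remains correctly
paired and the chance level is conservative (inflated) — visible in the
synthetic studies, where 6-trial calibration blocks give individual-model
chance thresholds far above the generalized-model ones (whose pools contain
42+ trials).  And chance correlations evaluated on short segments of
band-limited signals are intrinsically high; evaluation windows should span
many cycles of the kinematics.

**Statistics.**  Pairwise two-tailed Wilcoxon signed-rank tests compare
(strategy, space) conditions, paired on (participant, session, block,
kinematic), after grouping kinematics into position, velocity and
non-linear; scipy's exact distribution is used where available (small n, no
zeros/ties) with Pratt zero-handling otherwise.  P-values are
Benjamini–Hochberg adjusted within each (kinematic group, metric) family.
All-zero difference vectors are degenerate and reported as NaN rather than
as a rejection.

## Decoding patterns

Decoder weights are transformed to forward-model patterns,

    A = (1/g) Sigma_Y W Sigma_Z^(-1/2),

where `W` is the feature-to-kinematic weight map (D x 6) — this orientation
makes the transform conformable and recovers the true forward mixing in a
noiseless linear simulation (|cosine| > 0.99, the Haufe-style recovery
test) — `Sigma_Y` and `Sigma_Z` are properly 1/n-normalized covariances
(not the raw training inner products), and the inverse square root is the
symmetric one (eigenvalue floor 1e-12).  The normalizer `g` is a
model-specific global field power: the median, over 10,000 sampled
within-trial time points, of the standard deviation across source
components of the trial-averaged source-projected training pool.  Since
projection and trial-averaging are linear and commute, the per-index
standard deviations are precomputed once and the permutation loop reduces
to sampling indices — numerically identical to the naive procedure.  GFP
requires equal-length trials; `g = 0` (e.g. spatially constant projections)
is a guarded degenerate case.  Pattern collections are embedded in 2-D by
t-SNE, one embedding per kinematic, after normalizing each pattern by its
maximum absolute entry (perplexity 30 or `(n-1)/3` if smaller, fixed seed,
PCA initialization).

## Numerical and design choices

* Filters: zero-phase (forward-backward) 4th-order Butterworth; polyphase
  resampling with exact integer ratios.  Filter family and order are
  conventional choices; zero phase protects the feature–kinematics pairing.
* Indexing: 0-based, half-open trial intervals everywhere.
* `lam` is applied once per batch; within-batch weighting is uniform.
* Chance retraining reuses the matched model's `A` (no per-shuffle knee
  re-selection) and exploits that the feature-side moments are invariant
  under kinematic shuffling (only the cross terms are recomputed).
* Degenerate inputs: constant series give NaN correlations with a warning;
  perfect reconstruction gives +inf SNR; empty ROIs, single-channel CAR,
  positive lags, unknown strategies/modes all raise immediately.
* Random streams: a single seed fans out through `numpy` `SeedSequence`
  spawning, per stage and per participant, so stages are individually
  reproducible and a rerun of the orchestrated pipeline is bit-identical.

## Problem sizes used by the test suite and acceptance script

Unit tests run on miniature studies (2–3 participants, 84 source
locations, 10–20 s trials).  The headline transfer test uses the default
desk-scale study — 8 participants x 3 sessions x 3 blocks of 120 s at 32
channels / 500 locations — with 10 chance repeats per model and
60-s evaluation windows for chance retraining.  The calibration test uses
200 replicates of 20 chance repeats each.  `scripts/acceptance.py` runs the
same checks with a 6-participant, 90-s-block study and 100 calibration
replicates.  These sizes are the package's own desk-scale defaults; the
full-scale configuration (10 participants, 60 channels, 5000 locations,
50-component ceiling, 100 chance repeats) remains available through
`StudyDesign` and `DecoderConfig`.

## Known limitations

* The lead field is geometric, not anatomical; localization statements
  transfer to real EEG only qualitatively.
* The AR(1) transition is a crude model of quasi-periodic pursuit
  kinematics; the `q_scale` inflation compensates its misspecification
  rather than fixing it (a higher-order or oscillator transition would).
* Chance levels at small trial counts are conservative (fixed points of
  the permutation), see above.
* The sensor-space and source-space pipelines share one lead field per
  study; per-session electrode repositioning (a real-world source of
  across-session drift) is not modeled, only coupling drift is.
* No backward smoothing pass; the filter is strictly causal.
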