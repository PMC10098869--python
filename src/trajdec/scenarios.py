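"""Simulated-online transfer-learning scenarios.

A leave-one-participant-out (LOPO) generalized decoder, trained on the pooled
session-1 calibration (0% feedback) blocks of every *other* participant, is
the starting model for each participant.  Four update strategies then govern
how the decoder evolves over the participant's three sessions:

* ``Gen``   — the LOPO model is applied everywhere, never updated.
* ``GenC``  — after each session's 0% block, the pooled covariance state is
  cumulatively updated (lam = 1) with that block and the cascade refit
  (models GenC1..GenC3).
* ``Ind``   — a fresh individual model is fit from the current session's 0%
  block alone (Ind1..Ind3).
* ``IndC``  — the individual covariance state accumulates the 0% blocks of
  sessions 1..s (IndC2, IndC3; IndC1 coincides with Ind1).

Every 0% block is decoded with the model carried in from before that block
(causality), and model updates happen only at the end of 0% blocks.  Across
the four strategies a 3-session design yields 9 unique models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import evaluation, preprocess, rewpls, sourcespace, srukf
from .containers import LaggedFeatures
from .preprocess import PreprocessConfig
from .synthgen import SyntheticStudy

__all__ = [
    "DecoderConfig",
    "DecoderModel",
    "StudyFeatures",
    "enumerate_unique_models",
    "train_lopo",
    "run_strategy",
    "fit_decoder",
]

STRATEGIES = ("Gen", "GenC", "Ind", "IndC")
FEATURE_SPACES = ("sensor", "source")
CALIBRATION_BLOCK = "0"


@dataclass
class DecoderConfig:
    a_max: int = 50
    n_folds: int = 10
    lam: float = 1.0
    alpha_s: float = 1e-3
    beta_s: float = 2.0
    kappa_s: float = 0.0
    inverse_alpha: float | None = None
    diag_loading: float = 0.01


@dataclass
class DecoderModel:
    """A fitted PLS + SR-UKF cascade with its covariance state."""

    name: str
    pls: rewpls.PLSModel
    ukf: srukf.UKFModel
    state: rewpls.CovarianceState
    n_components: int
    training_blocks: tuple = ()

    def decode(self, features: np.ndarray) -> np.ndarray:
        """Decode a lagged feature block into (6, T) extended kinematics."""
        _, latents = rewpls.predict(self.pls, features)
        return srukf.run_srukf(self.ukf, latents)


def enumerate_unique_models(n_sessions: int = 3) -> list[str]:
    """Names of the unique fitted models across all four strategies.

    IndC1 coincides with Ind1, so a 3-session design yields 9 unique models
    and a single-session design collapses to 3.
    """
    if n_sessions < 1:
        raise ValueError("need at least one session")
    names = ["Gen"]
    names += [f"GenC{s}" for s in range(1, n_sessions + 1)]
    names += [f"Ind{s}" for s in range(1, n_sessions + 1)]
    names += [f"IndC{s}" for s in range(2, n_sessions + 1)]
    return names


class StudyFeatures:
    """Per-block lagged features and aligned extended kinematics.

    Extraction per block: conditioning chain -> common average reference ->
    (source space only: sLORETA projection + ROI scouting, with the noise
    covariance estimated from the participant's processed noise-only block)
    -> lag expansion, with the kinematics resampled to the decoding rate,
    extended with distance and speed, and subset to the surviving columns.
    """

    def __init__(
        self,
        study: SyntheticStudy,
        space: str = "sensor",
        pre_cfg: PreprocessConfig | None = None,
        cfg: DecoderConfig | None = None,
    ) -> None:
        if space not in FEATURE_SPACES:
            raise ValueError(f"unknown feature space {space!r}")
        self.study = study
        self.space = space
        self.pre_cfg = pre_cfg or PreprocessConfig()
        self.cfg = cfg or DecoderConfig()
        self._cache: dict = {}
        self._kernel = None
        self._scouting = None
        if space == "source":
            self._prepare_inverse()

    def _prepare_inverse(self) -> None:
        lf = self.study.leadfield
        # CAR-compatible lead field: the pipeline references data to the
        # common average, so the forward model seen by the kernel is M G.
        gain_car = lf.gain - lf.gain.mean(axis=0, keepdims=True)
        lf_car = type(lf)(
            gain=gain_car,
            source_positions=lf.source_positions,
            orientations=lf.orientations,
            roi_map=lf.roi_map,
            electrode_positions=lf.electrode_positions,
        )
        pooled = []
        for p, rec in self.study.noise_blocks.items():
            proc = preprocess.common_average_reference(
                preprocess.filter_chain(rec, self.pre_cfg)
            )
            pooled.append(proc.data)
        noise_cov = sourcespace.estimate_noise_covariance(
            pooled, diag_loading=self.cfg.diag_loading
        )
        self._kernel = sourcespace.sloreta_kernel(
            lf_car, noise_cov, alpha=self.cfg.inverse_alpha
        )
        self._scouting = sourcespace.build_scouting_matrix(lf_car)
        self._projector = self._scouting.matrix @ self._kernel.kernel

    def block(self, participant: int, session: int, block: str):
        """Return ``(features, targets, trials)`` for one measurement block.

        ``features`` is the (L*F, T) lagged feature matrix, ``targets`` the
        aligned (6, T) extended kinematics, ``trials`` the trial boundaries in
        the lagged indexing.
        """
        key = (participant, session, block)
        if key in self._cache:
            return self._cache[key]
        rec = self.study.recordings[key]
        kin = self.study.kinematics[key]
        proc = preprocess.common_average_reference(
            preprocess.filter_chain(rec, self.pre_cfg)
        )
        if self.space == "source":
            feats = self._projector @ proc.data
            labels = tuple(
                f"{roi}_{comp}"
                for roi in self._scouting.roi_labels
                for comp in "xyz"
            )
        else:
            feats = proc.data
            labels = proc.ch_names
        lagged = preprocess.lag_expand(
            feats, proc.trials, self.pre_cfg.lags, feature_labels=labels
        )
        kin20 = preprocess.resample_kinematics(kin, self.pre_cfg.out_fs)
        z_ext = evaluation.extend_kinematics(kin20.as_matrix())
        z_ext = z_ext[:, lagged.kept_columns]
        out = (lagged.data, z_ext, lagged.trials)
        self._cache[key] = out
        return out


def fit_decoder(
    name: str,
    blocks: list[tuple[np.ndarray, np.ndarray]],
    cfg: DecoderConfig,
    state: rewpls.CovarianceState | None = None,
    training_blocks: tuple = (),
) -> DecoderModel:
    """Fit the PLS + SR-UKF cascade on a pool of feature/target blocks.

    The covariance state is accumulated batch-wise over the blocks (one
    discount per block); the component count is re-selected at every fit by
    the cross-validated knee rule on the pooled raw data.
    """
    y_pool = np.hstack([y for y, _ in blocks])
    z_pool = np.hstack([z for _, z in blocks])
    if state is None:
        state = rewpls.CovarianceState.initial(
            y_pool.shape[0], z_pool.shape[0], lam=cfg.lam
        )
    for y, z in blocks:
        rewpls.update_covariances(state, y, z)
    a_star, _ = rewpls.select_components(
        y_pool, z_pool, a_max=cfg.a_max, n_folds=cfg.n_folds
    )
    pls = rewpls.fit_from_covariances(state, a_star)
    _, latents = rewpls.predict(pls, y_pool)
    ukf = srukf.fit_ukf_models(
        latents, z_pool, alpha_s=cfg.alpha_s, beta_s=cfg.beta_s, kappa_s=cfg.kappa_s
    )
    return DecoderModel(
        name=name, pls=pls, ukf=ukf, state=state,
        n_components=pls.n_components, training_blocks=tuple(training_blocks),
    )


def _cv_pool(features: StudyFeatures, keys) -> list:
    return [features.block(*key)[:2] for key in keys]


def train_lopo(
    study: SyntheticStudy,
    held_out_participant: int,
    features: StudyFeatures,
    cfg: DecoderConfig | None = None,
) -> DecoderModel:
    """Train the LOPO generalized decoder for one held-out participant.

    The training pool is the session-1 calibration (0% feedback) block of
    every other participant; the covariance state accumulates the pool at
    lam = 1 and both cascade stages are fit on the pooled data.
    """
    cfg = cfg or DecoderConfig()
    if held_out_participant not in study.participants:
        raise ValueError(f"participant {held_out_participant} not in study")
    if study.design.n_participants < 2:
        raise ValueError("LOPO needs at least 2 participants")
    keys = [
        (p, 1, CALIBRATION_BLOCK)
        for p in study.participants
        if p != held_out_participant
    ]
    return fit_decoder("Gen", _cv_pool(features, keys), cfg, training_blocks=tuple(keys))


def run_strategy(
    study: SyntheticStudy,
    participant: int,
    strategy: str,
    features: StudyFeatures,
    cfg: DecoderConfig | None = None,
    lopo_model: DecoderModel | None = None,
) -> tuple[dict, dict]:
    """Run one update strategy for one participant.

    Returns ``(decoded, registry)``: decoded kinematics per
    ``(session, block)`` and the fitted models by name.  Every 0% block is
    decoded with the model carried in from before that block; updates happen
    only after 0% blocks.
    """
    cfg = cfg or DecoderConfig()
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; use one of {STRATEGIES}")
    if lopo_model is None:
        lopo_model = train_lopo(study, participant, features, cfg)

    design = study.design
    decoded: dict = {}
    registry: dict = {"Gen": lopo_model}
    current = lopo_model
    cum_state = None
    cum_keys: list = []

    for session in range(1, design.n_sessions + 1):
        for block in design.blocks:
            key = (participant, session, block)
            y, z, trials = features.block(*key)
            if block == CALIBRATION_BLOCK:
                decoded[(session, block)] = current.decode(y)
                if strategy == "Gen":
                    continue
                new_key = (participant, session, block)
                if strategy == "GenC":
                    cum_keys.append(new_key)
                    pool_keys = list(lopo_model.training_blocks) + cum_keys
                    name = f"GenC{session}"
                elif strategy == "Ind":
                    pool_keys = [new_key]
                    name = f"Ind{session}"
                else:  # IndC
                    cum_keys.append(new_key)
                    pool_keys = list(cum_keys)
                    name = f"Ind{session}" if session == 1 else f"IndC{session}"
                current = fit_decoder(
                    name, _cv_pool(features, pool_keys), cfg,
                    training_blocks=tuple(pool_keys),
                )
                registry[name] = current
            else:
                decoded[(session, block)] = current.decode(y)
    return decoded, registry
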