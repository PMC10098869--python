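"""Configuration and end-to-end orchestration.

``RunConfig`` is a strictly validated, section-structured configuration
(unknown keys are rejected before any computation); ``run_pipeline`` ties the
stages together: simulate -> preprocess/feature extraction -> the four update
strategies per feature space -> metric tables, chance levels, pairwise
statistics and decoding patterns, all written to a results directory together
with a manifest recording the configuration hash and seeds.

A single global seed fans out to per-stage seed sequences, so a rerun with
the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, patterns, scenarios, synthgen
from .preprocess import PreprocessConfig
from .scenarios import DecoderConfig, StudyFeatures
from .synthgen import StudyDesign

__all__ = [
    "RunConfig",
    "EvaluationConfig",
    "PatternConfig",
    "run_pipeline",
    "load_config",
    "transfer_summary",
]

logger = logging.getLogger("trajdec")


class ConfigError(ValueError):
    pass


@dataclass
class EvaluationConfig:
    n_repeats: int = 10
    percentile: float = 95.0
    fdr_alpha: float = 0.05
    #: unique-model names whose chance level is computed (empty = skip).
    chance_models: tuple[str, ...] = ("Gen",)
    #: optional truncation of evaluation sets for chance retraining.
    chance_eval_samples: int | None = None


@dataclass
class PatternConfig:
    n_perm: int = 10_000
    perplexity: float = 30.0


@dataclass
class RunConfig:
    study: StudyDesign = field(default_factory=StudyDesign)
    coupling_mode: str = "shared"
    snr_db: float = 10.0
    seed: int = 0
    spaces: tuple[str, ...] = ("sensor", "source")
    strategies: tuple[str, ...] = scenarios.STRATEGIES
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    pattern: PatternConfig = field(default_factory=PatternConfig)

    def validate(self) -> None:
        self.study.validate()
        for sp in self.spaces:
            if sp not in scenarios.FEATURE_SPACES:
                raise ConfigError(f"unknown feature space {sp!r}")
        for st in self.strategies:
            if st not in scenarios.STRATEGIES:
                raise ConfigError(f"unknown strategy {st!r}")
        if self.coupling_mode not in synthgen.COUPLING_MODES:
            raise ConfigError(f"unknown coupling_mode {self.coupling_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


_SECTION_TYPES = {
    "study": StudyDesign,
    "preprocess": PreprocessConfig,
    "decoder": DecoderConfig,
    "evaluation": EvaluationConfig,
    "pattern": PatternConfig,
}


def load_config(source) -> RunConfig:
    """Build a RunConfig from a mapping, a YAML/JSON file path, or YAML text.

    Unknown keys anywhere in the document raise ``ConfigError`` before any
    computation starts.
    """
    if isinstance(source, (str, Path)) and Path(source).exists():
        data = yaml.safe_load(Path(source).read_text())
    elif isinstance(source, str):
        data = yaml.safe_load(source)
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    kwargs = {}
    for key, value in data.items():
        if key not in top_fields:
            raise ConfigError(f"unknown configuration key {key!r}")
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            section_fields = {f.name for f in dataclasses.fields(_SECTION_TYPES[key])}
            unknown = set(value) - section_fields
            if unknown:
                raise ConfigError(f"unknown key(s) in section {key!r}: {sorted(unknown)}")
            value = {
                k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
            }
            value = _SECTION_TYPES[key](**value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def run_pipeline(config: RunConfig | dict | str | Path, out_dir: str | Path) -> Path:
    """Run the full analysis and write results under ``out_dir``.

    Outputs: ``metrics.csv`` (per participant/session/block/strategy/space/
    kinematic correlations and SNRs), ``chance.json`` (per-participant and
    group chance thresholds for the configured models), ``stats.csv``
    (pairwise Wilcoxon + FDR), ``patterns.csv`` and ``embedding.csv`` (source-
    space decoding patterns), and ``manifest.json``.
    """
    if not isinstance(config, RunConfig):
        config = load_config(config)
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    root_ss = np.random.SeedSequence(config.seed)
    ss_study, ss_chance, ss_pattern = root_ss.spawn(3)
    study_seed = int(ss_study.generate_state(1)[0] % (2**31))

    logger.info("simulating study (%s coupling, %.1f dB SNR)", config.coupling_mode, config.snr_db)
    study = synthgen.gen_study(
        config.study, coupling_mode=config.coupling_mode,
        snr_db=config.snr_db, seed=study_seed,
    )

    metric_rows = []
    chance_out: dict = {}
    pattern_rows = []
    embed_rows = []
    truth_cache: dict = {}

    for space in config.spaces:
        logger.info("extracting %s-space features", space)
        feats = StudyFeatures(study, space=space, pre_cfg=config.preprocess, cfg=config.decoder)
        registries: dict = {}
        for p in study.participants:
            lopo = scenarios.train_lopo(study, p, feats, config.decoder)
            registry_all: dict = {}
            for strategy in config.strategies:
                decoded, registry = scenarios.run_strategy(
                    study, p, strategy, feats, config.decoder, lopo_model=lopo
                )
                registry_all.update(registry)
                for (session, block), z_hat in decoded.items():
                    _, z_true, _ = feats.block(p, session, block)
                    metric_rows.append(
                        evaluation.block_metrics(
                            z_hat, z_true,
                            participant=p, session=session, block=block,
                            strategy=strategy, space=space,
                        )
                    )
            registries[p] = registry_all

            # chance levels for the configured unique models
            rng_chance = np.random.default_rng(ss_chance.spawn(1)[0])
            for model_name in config.evaluation.chance_models:
                model = registry_all.get(model_name)
                if model is None:
                    continue
                train_blocks = [feats.block(*key) for key in model.training_blocks]
                y_tr = np.hstack([b[0] for b in train_blocks])
                z_tr = np.hstack([b[1] for b in train_blocks])
                trials = _stack_trials([b[2] for b in train_blocks])
                eval_sets = [
                    feats.block(p, s, b)[:2]
                    for s in range(1, study.design.n_sessions + 1)
                    for b in study.design.blocks
                ]
                dist = evaluation.chance_distribution(
                    y_tr, z_tr, trials, eval_sets,
                    n_components=model.n_components,
                    n_repeats=config.evaluation.n_repeats,
                    rng=rng_chance,
                    eval_samples=config.evaluation.chance_eval_samples,
                )
                thr = evaluation.chance_threshold(dist, config.evaluation.percentile)
                chance_out.setdefault(space, {}).setdefault(model_name, {})[str(p)] = {
                    name: float(v)
                    for name, v in zip(evaluation.EXTENDED_KINEMATIC_NAMES, thr)
                }

        # decoding patterns (source space carries the interpretable geometry)
        if space == "source":
            rng_pat = np.random.default_rng(ss_pattern.spawn(1)[0])
            pat_vectors: dict = {}
            for p, registry_all in registries.items():
                for name, model in registry_all.items():
                    blocks = model.training_blocks or ((p, 1, "0"),)
                    stack = _training_sensor_stack(study, blocks)
                    g = patterns.model_gfp(
                        stack, feats._kernel.kernel,
                        n_perm=config.pattern.n_perm, seed=rng_pat,
                    )
                    sigma_y, _ = patterns.normalized_covariances(model.state)
                    z_blocks = [feats.block(*k)[1] for k in model.training_blocks] or [
                        feats.block(p, 1, "0")[1]
                    ]
                    z_cat = np.hstack(z_blocks)
                    sigma_z = np.cov(z_cat, bias=True)
                    pat = patterns.decoding_pattern(model.pls, sigma_y, sigma_z, g)
                    for ki, kin in enumerate(evaluation.EXTENDED_KINEMATIC_NAMES):
                        pat_vectors.setdefault(kin, []).append(
                            (p, name, pat.pattern[:, ki])
                        )
                    pattern_rows.append(
                        dict(participant=p, model=name, gfp=g,
                             frob=float(np.linalg.norm(pat.pattern)))
                    )
            for kin, entries in pat_vectors.items():
                if len(entries) < 3:
                    continue
                mat = np.vstack([vec for _, _, vec in entries])
                coords = patterns.embed_patterns(
                    mat, perplexity=config.pattern.perplexity, seed=config.seed
                )
                for (p, name, _), (d1, d2) in zip(entries, coords):
                    embed_rows.append(
                        dict(participant=p, model=name, kinematic=kin,
                             dim1=float(d1), dim2=float(d2))
                    )

    metrics = pd.concat(metric_rows, ignore_index=True)
    metrics.to_csv(out / "metrics.csv", index=False)

    group_chance = {
        space: {
            model: {
                kin: float(np.median([per_p[kin] for per_p in data.values()]))
                for kin in evaluation.EXTENDED_KINEMATIC_NAMES
            }
            for model, data in by_model.items()
        }
        for space, by_model in chance_out.items()
    }
    (out / "chance.json").write_text(
        json.dumps({"per_participant": chance_out, "group": group_chance}, indent=2)
    )

    stats = evaluation.compare_strategies(metrics, alpha=config.evaluation.fdr_alpha)
    stats.to_csv(out / "stats.csv", index=False)

    if pattern_rows:
        pd.DataFrame(pattern_rows).to_csv(out / "patterns.csv", index=False)
    if embed_rows:
        pd.DataFrame(embed_rows).to_csv(out / "embedding.csv", index=False)

    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "study_seed": study_seed,
        "elapsed_s": round(time.time() - t0, 2),
        "n_metric_rows": int(len(metrics)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return out


def transfer_summary(
    coupling_mode: str,
    design: StudyDesign | None = None,
    snr_db: float = 10.0,
    seed: int = 0,
    space: str = "sensor",
    decoder: DecoderConfig | None = None,
    strategies: tuple[str, ...] = ("Gen", "Ind"),
    chance_repeats: int = 10,
    chance_eval_samples: int | None = 1200,
) -> dict:
    """Headline transfer-learning summary on one synthetic study.

    Runs the requested strategies over every participant of a freshly
    generated study and aggregates, over the feedback (50%/100%) blocks, the
    group-median absolute velocity correlation per strategy together with the
    matching trial-shuffled chance thresholds (95th percentile per
    participant, median across participants).

    Returns a dict with per-strategy ``median_r`` and ``chance_r`` (both
    pooled over the two velocity components), plus the per-participant values.
    """
    design = design or StudyDesign()
    decoder = decoder or DecoderConfig()
    root_ss = np.random.SeedSequence(seed)
    ss_study, ss_chance = root_ss.spawn(2)
    study = synthgen.gen_study(
        design, coupling_mode=coupling_mode, snr_db=snr_db,
        seed=int(ss_study.generate_state(1)[0] % (2**31)),
    )
    feats = StudyFeatures(study, space=space, cfg=decoder)
    eval_blocks = [b for b in design.blocks if b != "0"]
    vel_rows = (1, 3)

    out: dict = {s: {"r": [], "chance": []} for s in strategies}
    for p in study.participants:
        lopo = scenarios.train_lopo(study, p, feats, decoder)
        rng_chance = np.random.default_rng(ss_chance.spawn(1)[0])
        for strategy in strategies:
            decoded, registry = scenarios.run_strategy(
                study, p, strategy, feats, decoder, lopo_model=lopo
            )
            r_vals = []
            for (session, block), z_hat in decoded.items():
                if block not in eval_blocks:
                    continue
                _, z_true, _ = feats.block(p, session, block)
                r_vals += [
                    abs(evaluation.pearson_r(z_true[i], z_hat[i])) for i in vel_rows
                ]
            out[strategy]["r"].append(float(np.median(r_vals)))

            # chance thresholds for the models that decoded the eval blocks
            thr_vals = []
            model_sessions: dict = {}
            for session in range(1, design.n_sessions + 1):
                name = {
                    "Gen": "Gen",
                    "GenC": f"GenC{session}",
                    "Ind": f"Ind{session}",
                    "IndC": f"Ind{session}" if session == 1 else f"IndC{session}",
                }[strategy]
                model_sessions.setdefault(name, []).append(session)
            for name, sessions in model_sessions.items():
                model = registry[name]
                train = [feats.block(*k) for k in model.training_blocks]
                y_tr = np.hstack([b[0] for b in train])
                z_tr = np.hstack([b[1] for b in train])
                trials = _stack_trials([b[2] for b in train])
                eval_sets = [
                    feats.block(p, s, b)[:2] for s in sessions for b in eval_blocks
                ]
                dist = evaluation.chance_distribution(
                    y_tr, z_tr, trials, eval_sets,
                    n_components=model.n_components,
                    n_repeats=chance_repeats, rng=rng_chance,
                    eval_samples=chance_eval_samples,
                )
                thr = evaluation.chance_threshold(dist)
                thr_vals.append(np.median(thr[list(vel_rows)]))
            out[strategy]["chance"].append(float(np.median(thr_vals)))

    return {
        strategy: {
            "median_r": float(np.median(vals["r"])),
            "chance_r": float(np.median(vals["chance"])),
            "per_participant_r": vals["r"],
            "per_participant_chance": vals["chance"],
        }
        for strategy, vals in out.items()
    }


def _stack_trials(trial_lists) -> tuple:
    out = []
    offset = 0
    for trials in trial_lists:
        for a, b in trials:
            out.append((a + offset, b + offset))
        offset = out[-1][1]
    return tuple(out)


def _training_sensor_stack(study, training_blocks) -> np.ndarray:
    """Equal-length trial stack of raw sensor data over the training pool."""
    stacks = []
    for key in training_blocks:
        rec = study.recordings[key]
        for a, b in rec.trials:
            stacks.append(rec.data[:, a:b])
    length = min(s.shape[1] for s in stacks)
    return np.stack([s[:, :length] for s in stacks])
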