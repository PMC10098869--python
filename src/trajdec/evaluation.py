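"""Decoding metrics, trial-shuffled chance levels, and strategy comparisons.

Metrics are Pearson's correlation and a decoding SNR,
``10 log10(var(truth) / MSE(truth, decoded))`` in dB, with variance and MSE
both 1/n-normalized so that predicting the mean of the truth gives exactly
0 dB.  Group-level correlation distributions use absolute values of the
participant-level correlations.

Chance levels come from decoders retrained on trial-shuffled
feature-kinematics pairings: shuffling permutes the assignment of kinematic
trial segments to feature trials, which preserves the marginal content of both
streams while breaking their pairing.  The per-participant threshold is the
95th percentile (conservative ``higher`` order statistic) of the chance
correlation distribution; the group threshold is the median across
participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import EXTENDED_KINEMATIC_NAMES
from . import rewpls, srukf

__all__ = [
    "extend_kinematics",
    "pearson_r",
    "snr_db",
    "block_metrics",
    "shuffle_trials",
    "chance_distribution",
    "chance_threshold",
    "group_chance_level",
    "chance_plan",
    "compare_strategies",
    "KINEMATIC_GROUPS",
]

#: Kinematic grouping used for the statistical comparisons.
KINEMATIC_GROUPS = {
    "position": ("p_hor", "p_ver"),
    "velocity": ("v_hor", "v_ver"),
    "nonlinear": ("d", "s"),
}


def extend_kinematics(z: np.ndarray) -> np.ndarray:
    """Append distance and speed to the 4 linear kinematics.

    ``z`` is (4, T) ordered (p_hor, v_hor, p_ver, v_ver); the result appends
    ``d = sqrt(p_hor^2 + p_ver^2)`` and ``s = sqrt(v_hor^2 + v_ver^2)``.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[0] != 4:
        raise ValueError("expected 4 linear kinematics rows")
    d = np.hypot(z[0], z[2])
    s = np.hypot(z[1], z[3])
    return np.vstack([z, d, s])


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson's correlation coefficient; NaN (with a warning) for constant input."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        warnings.warn("correlation undefined for constant input", RuntimeWarning)
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def snr_db(x_truth: np.ndarray, y_decoded: np.ndarray) -> float:
    """Decoding SNR in dB; truth is the first argument.

    Both variance and MSE use 1/n normalization, so ``snr_db(x, mean(x)) == 0``
    exactly.  A perfect reconstruction returns +inf; constant truth is NaN.
    """
    x = np.asarray(x_truth, dtype=float).ravel()
    y = np.asarray(y_decoded, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    var = float(np.mean((x - x.mean()) ** 2))
    mse = float(np.mean((x - y) ** 2))
    if var == 0:
        warnings.warn("SNR undefined for constant truth", RuntimeWarning)
        return float("nan")
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(var / mse)


def block_metrics(
    decoded: np.ndarray,
    truth: np.ndarray,
    **keys,
) -> pd.DataFrame:
    """Tidy per-kinematic metric rows for one decoded block.

    ``decoded`` and ``truth`` are (6, T) extended kinematics; extra keyword
    arguments (participant, session, block, strategy, space, ...) become
    columns.
    """
    rows = []
    for i, name in enumerate(EXTENDED_KINEMATIC_NAMES):
        rows.append(
            dict(
                keys,
                kinematic=name,
                r=pearson_r(truth[i], decoded[i]),
                snr=snr_db(truth[i], decoded[i]),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trial-shuffled chance levels
# ---------------------------------------------------------------------------


def _equal_trial_segments(trials) -> int:
    lengths = {stop - start for start, stop in trials}
    if len(trials) < 2:
        raise ValueError("trial shuffling needs at least 2 trials")
    if len(lengths) != 1:
        raise ValueError("trial shuffling requires equal-length trials")
    return lengths.pop()


def shuffle_trials(z: np.ndarray, trials, rng: np.random.Generator) -> np.ndarray:
    """Permute the assignment of kinematic trial segments to trial slots.

    The multiset of trial segments is unchanged; only the pairing with the
    (unshuffled) features is interrupted.
    """
    _equal_trial_segments(trials)
    z = np.asarray(z, dtype=float)
    perm = rng.permutation(len(trials))
    out = z.copy()
    for slot, src in enumerate(perm):
        a, b = trials[slot]
        c, d = trials[src]
        out[:, a:b] = z[:, c:d]
    return out


def chance_distribution(
    train_features: np.ndarray,
    train_targets: np.ndarray,
    train_trials,
    eval_sets: list[tuple[np.ndarray, np.ndarray]],
    n_components: int,
    n_repeats: int = 100,
    rng: np.random.Generator | int | None = None,
    lam: float = 1.0,
    eval_samples: int | None = None,
) -> np.ndarray:
    """Absolute chance correlations from trial-shuffled decoder retraining.

    Per repeat the kinematic trial segments of the training pool are permuted,
    the PLS + SR-UKF cascade is retrained (reusing the matched model's
    component count), applied to every evaluation set, and the absolute
    correlations collected.  Returns an array of shape
    ``(n_repeats, n_eval_sets, 6)``.

    ``eval_samples`` optionally truncates each evaluation set (a shorter
    segment is enough to estimate a chance correlation).
    """
    rng = np.random.default_rng(rng)
    y = np.asarray(train_features, dtype=float)
    d = y.shape[0]
    m = np.asarray(train_targets).shape[0]
    # the feature-side moments do not depend on the kinematic shuffle: compute
    # them once and refresh only the cross terms per repeat (the training pool
    # enters as a single batch, which at lam = 1 equals the batched recursion)
    base = rewpls.CovarianceState.initial(d, m, lam=1.0)
    rewpls.update_covariances(base, y, np.zeros((m, y.shape[1])))
    out = np.empty((n_repeats, len(eval_sets), len(EXTENDED_KINEMATIC_NAMES)))
    for rep in range(n_repeats):
        z_shuf = shuffle_trials(train_targets, train_trials, rng)
        state = base.copy()
        state.cyz = y @ z_shuf.T
        state.sum_z = z_shuf.sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pls = rewpls.fit_from_covariances(state, n_components)
            _, latents = rewpls.predict(pls, y)
            ukf = srukf.fit_ukf_models(latents, z_shuf)
            for j, (y_eval, z_eval) in enumerate(eval_sets):
                if eval_samples is not None:
                    y_eval = y_eval[:, :eval_samples]
                    z_eval = z_eval[:, :eval_samples]
                _, e_eval = rewpls.predict(pls, y_eval)
                z_hat = srukf.run_srukf(ukf, e_eval)
                for i in range(len(EXTENDED_KINEMATIC_NAMES)):
                    out[rep, j, i] = abs(pearson_r(z_eval[i], z_hat[i]))
    return out


def chance_threshold(distribution: np.ndarray, percentile: float = 95.0) -> np.ndarray:
    """Per-kinematic chance threshold from a ``chance_distribution`` output.

    Pools repeats and evaluation sets per kinematic and takes the requested
    percentile with the conservative ``higher`` order statistic.
    """
    flat = distribution.reshape(-1, distribution.shape[-1])
    return np.percentile(flat, percentile, axis=0, method="higher")


def group_chance_level(per_participant: list[np.ndarray]) -> np.ndarray:
    """Median across participants of per-participant thresholds."""
    return np.median(np.vstack(per_participant), axis=0)


def chance_plan(
    n_participants: int, unique_models, n_repeats: int = 100
) -> list[tuple[int, str, int]]:
    """Enumerate every chance-level model to be trained: one per
    (participant, unique model, repeat)."""
    return [
        (p, name, rep)
        for p in range(n_participants)
        for name in unique_models
        for rep in range(n_repeats)
    ]


# ---------------------------------------------------------------------------
# strategy comparisons
# ---------------------------------------------------------------------------


def compare_strategies(
    metric_table: pd.DataFrame,
    metrics: tuple[str, ...] = ("r", "snr"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise Wilcoxon signed-rank tests between (strategy, space) conditions.

    Kinematics are grouped into position, velocity and non-linear; correlations
    enter as absolute values.  Samples are paired on
    (participant, session, block, kinematic) within each group, and p-values
    are Benjamini-Hochberg adjusted within each (kinematic group, metric)
    family.
    """
    table = metric_table.copy()
    table["abs_r"] = table["r"].abs()
    conds = sorted(
        table[["strategy", "space"]].drop_duplicates().itertuples(index=False, name=None)
    )
    key_cols = ["participant", "session", "block", "kinematic"]
    rows = []
    for group, kin_names in KINEMATIC_GROUPS.items():
        sub = table[table["kinematic"].isin(kin_names)]
        for metric in metrics:
            col = "abs_r" if metric == "r" else metric
            wide = sub.pivot_table(
                index=key_cols, columns=["strategy", "space"], values=col
            )
            family = []
            for (s1, sp1), (s2, sp2) in combinations(conds, 2):
                if (s1, sp1) not in wide.columns or (s2, sp2) not in wide.columns:
                    continue
                pair = wide[[(s1, sp1), (s2, sp2)]].dropna()
                diff = pair.iloc[:, 0] - pair.iloc[:, 1]
                if len(diff) < 2 or np.allclose(diff, 0.0):
                    p_raw = float("nan")
                else:
                    p_raw = float(
                        stats.wilcoxon(
                            diff, zero_method="pratt", alternative="two-sided",
                            method="auto",
                        ).pvalue
                    )
                family.append(
                    dict(
                        group=group, metric=metric,
                        strategy_a=s1, space_a=sp1,
                        strategy_b=s2, space_b=sp2,
                        n=len(diff), p_raw=p_raw,
                    )
                )
            if not family:
                continue
            pvals = np.asarray([f["p_raw"] for f in family])
            mask = np.isfinite(pvals)
            adj = np.full_like(pvals, np.nan)
            if mask.any():
                adj[mask] = multipletests(pvals[mask], alpha=alpha, method="fdr_bh")[1]
            for f, p_adj in zip(family, adj):
                f["p_fdr"] = float(p_adj) if np.isfinite(p_adj) else float("nan")
                rows.append(f)
    return pd.DataFrame(rows)
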