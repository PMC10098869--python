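"""Decoding-pattern analysis: forward-model transforms of decoder weights.

Raw decoder weights tell you what the decoder extracts, not where the
information lives; the forward-model (Haufe-style) transform

    A = (1 / g) * Sigma_Y W Sigma_Z^(-1/2)

turns the feature-to-kinematic weight map ``W`` (D x 6) into an interpretable
pattern by multiplying with the feature covariance ``Sigma_Y`` and the
symmetric inverse square root of the extended-kinematics covariance
``Sigma_Z``.  Both covariances are properly 1/n-normalized (not the raw
training inner products).  ``g`` is a model-specific global field power that
removes across-participant scale differences; it is estimated by a permutation
procedure over the source-projected training pool.

Pattern collections are embedded in 2-D with t-SNE, one embedding per
kinematic, after normalizing each pattern by its maximum absolute entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.manifold import TSNE

from .containers import EXTENDED_KINEMATIC_NAMES
from .rewpls import CovarianceState, PLSModel

__all__ = [
    "DecodingPattern",
    "model_gfp",
    "decoding_pattern",
    "normalized_covariances",
    "embed_patterns",
]


@dataclass
class DecodingPattern:
    """Pattern matrix (features x 6 extended kinematics) with its inputs."""

    pattern: np.ndarray
    sigma_y: np.ndarray
    sigma_z: np.ndarray
    gfp: float
    kinematic_names: tuple[str, ...] = EXTENDED_KINEMATIC_NAMES

    def column(self, kinematic: str) -> np.ndarray:
        return self.pattern[:, self.kinematic_names.index(kinematic)]


def model_gfp(
    trial_stack: np.ndarray,
    kernel: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Model-specific global field power by a permutation procedure.

    ``trial_stack`` is ``(n_trials, P, L)`` — the training sensor pool cut
    into equal-length trials.  Per permutation a single within-trial time
    index is drawn, the source-projected sample is averaged over trials, and
    the standard deviation over source components taken; ``g`` is the median
    over permutations.  Projection and trial averaging commute (both linear),
    so the per-index standard deviations are precomputed once.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    stack = np.asarray(trial_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("trial_stack must be (n_trials, channels, samples)")
    rng = np.random.default_rng(seed)
    mean_trial = stack.mean(axis=0)                 # (P, L)
    projected = kernel @ mean_trial                 # (Q, L)
    stds = projected.std(axis=0)                    # per time index
    idx = rng.integers(0, stds.size, size=n_perm)
    return float(np.median(stds[idx]))


def normalized_covariances(
    state: CovarianceState,
) -> tuple[np.ndarray, np.ndarray]:
    """1/n-normalized feature covariance from a covariance state.

    Returns ``(Sigma_Y, mu_y)``; the extended-kinematics covariance is not
    tracked by the state and must be computed from the training targets.
    """
    cyy, _, mu_y, _ = state.centered()
    return cyy / state.weight, mu_y


def _sym_isqrt(mat: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (mat + mat.T))
    if vals.max() <= 0:
        raise ValueError("covariance is not positive definite")
    if vals.min() <= floor * vals.max():
        raise ValueError("singular extended-kinematics covariance")
    return (vecs / np.sqrt(vals)) @ vecs.T


def decoding_pattern(
    model: PLSModel | np.ndarray,
    sigma_y: np.ndarray,
    sigma_z: np.ndarray,
    gfp: float,
) -> DecodingPattern:
    """Forward-model transform of the feature-to-kinematic weight map.

    ``model`` is a fitted PLS model (its regression coefficients are the
    weight map) or the (D, M) weight matrix itself.  The inverse square root
    of ``sigma_z`` is the symmetric one.
    """
    w_fk = model.coef if isinstance(model, PLSModel) else np.asarray(model, dtype=float)
    if gfp <= 0:
        raise ValueError("degenerate global field power (g <= 0)")
    isq = _sym_isqrt(np.asarray(sigma_z, dtype=float))
    pattern = (sigma_y @ w_fk @ isq) / gfp
    return DecodingPattern(
        pattern=pattern, sigma_y=np.asarray(sigma_y), sigma_z=np.asarray(sigma_z),
        gfp=float(gfp),
    )


def embed_patterns(
    patterns: np.ndarray,
    perplexity: float = 30.0,
    seed: int = 0,
    n_iter: int = 1000,
) -> np.ndarray:
    """Embed a pattern collection in 2-D with t-SNE.

    ``patterns`` is ``(n_patterns, D)`` — one row per model, typically the
    pattern column of a single kinematic across models.  Each pattern is
    normalized by its maximum absolute entry before embedding; the embedding
    is deterministic for a fixed seed.
    """
    x = np.atleast_2d(np.asarray(patterns, dtype=float))
    if x.shape[0] < 3:
        raise ValueError("need at least 3 patterns to embed")
    maxima = np.abs(x).max(axis=1)
    if np.any(maxima == 0):
        raise ValueError("all-zero pattern cannot be normalized")
    x = x / maxima[:, None]
    eff_perp = min(perplexity, max(1.0, (x.shape[0] - 1) / 3.0))
    tsne = TSNE(
        n_components=2,
        perplexity=eff_perp,
        random_state=seed,
        init="pca",
        max_iter=n_iter,
    )
    return tsne.fit_transform(x)
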