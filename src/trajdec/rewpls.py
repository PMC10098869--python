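"""Recursive exponentially weighted partial least squares (REW-PLS).

A PLS regression fitted from recursively updated (non-normalized) covariance
matrices rather than from the raw data: per batch,

    (Y Y')_t = lam * (Y Y')_t-1 + Y_b Y_b'
    (Y Z')_t = lam * (Y Z')_t-1 + Y_b Z_b'

with a forgetting factor ``lam`` in (0, 1].  At ``lam = 1`` the state equals
the inner products of the concatenated data, so the covariance-space fit is
exactly equivalent to a batch PLS fit — the property the oracle tests assert.

The state additionally tracks exponentially weighted running sums of features
and targets so that the covariances can be centered at fit time; fitting uses
the modified kernel algorithm #2 (Dayal & MacGregor), which consumes only
``(Y Y')`` and ``(Y Z')`` and therefore has a memory footprint independent of
the number of training samples.

Convention: feature matrices are ``(D, n)`` and target matrices ``(M, n)``
with samples as columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CovarianceState",
    "PLSModel",
    "update_covariances",
    "fit_from_covariances",
    "select_components",
    "knee_point",
    "predict",
]


@dataclass
class CovarianceState:
    """Running non-normalized covariance pair plus weighted first moments."""

    cyy: np.ndarray          # (D, D)
    cyz: np.ndarray          # (D, M)
    sum_y: np.ndarray        # (D,)
    sum_z: np.ndarray        # (M,)
    weight: float            # exponentially weighted sample count
    lam: float = 1.0
    n_batches: int = 0

    @classmethod
    def initial(cls, n_features: int, n_targets: int, lam: float = 1.0) -> "CovarianceState":
        if not (0.0 < lam <= 1.0):
            raise ValueError("forgetting factor lam must be in (0, 1]")
        return cls(
            cyy=np.zeros((n_features, n_features)),
            cyz=np.zeros((n_features, n_targets)),
            sum_y=np.zeros(n_features),
            sum_z=np.zeros(n_targets),
            weight=0.0,
            lam=lam,
        )

    @property
    def n_features(self) -> int:
        return self.cyy.shape[0]

    @property
    def n_targets(self) -> int:
        return self.cyz.shape[1]

    def copy(self) -> "CovarianceState":
        return CovarianceState(
            cyy=self.cyy.copy(), cyz=self.cyz.copy(),
            sum_y=self.sum_y.copy(), sum_z=self.sum_z.copy(),
            weight=self.weight, lam=self.lam, n_batches=self.n_batches,
        )

    def centered(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Centered covariances and the weighted means (mu_y, mu_z)."""
        if self.weight <= 0:
            raise ValueError("empty covariance state")
        mu_y = self.sum_y / self.weight
        mu_z = self.sum_z / self.weight
        cyy = self.cyy - np.outer(self.sum_y, self.sum_y) / self.weight
        cyz = self.cyz - np.outer(self.sum_y, self.sum_z) / self.weight
        return cyy, cyz, mu_y, mu_z


def update_covariances(
    state: CovarianceState,
    batch_y: np.ndarray,
    batch_z: np.ndarray,
    lam: float | None = None,
) -> CovarianceState:
    """Discount the previous state once by ``lam`` and add the batch's inner
    products.  Mutates and returns ``state``."""
    y = np.atleast_2d(np.asarray(batch_y, dtype=float))
    z = np.atleast_2d(np.asarray(batch_z, dtype=float))
    if y.shape[1] != z.shape[1]:
        raise ValueError("feature and target batches must have paired columns")
    if y.shape[0] != state.n_features or z.shape[0] != state.n_targets:
        raise ValueError("batch dimensions do not match the covariance state")
    if lam is not None:
        if not (0.0 <= lam <= 1.0):
            raise ValueError("lam must be in [0, 1]")
        state.lam = float(lam)
    lam_eff = state.lam
    state.cyy = lam_eff * state.cyy + y @ y.T
    state.cyz = lam_eff * state.cyz + y @ z.T
    state.sum_y = lam_eff * state.sum_y + y.sum(axis=1)
    state.sum_z = lam_eff * state.sum_z + z.sum(axis=1)
    state.weight = lam_eff * state.weight + y.shape[1]
    state.n_batches += 1
    return state


@dataclass
class PLSModel:
    """A fitted PLS regression.

    ``weights`` (A x D) maps centered features to latent scores,
    ``E = weights @ (y - mean_y)``; ``coef`` (D x M) are the regression
    coefficients so predictions are ``coef' (y - mean_y) + mean_z``.
    """

    weights: np.ndarray          # (A, D) latent projection (rows r_a)
    loadings: np.ndarray         # (D, A) feature loadings p_a
    y_loadings: np.ndarray       # (M, A) target loadings q_a
    coef: np.ndarray             # (D, M)
    mean_y: np.ndarray
    mean_z: np.ndarray
    n_components: int
    lam: float = 1.0

    @property
    def intercept(self) -> np.ndarray:
        return self.mean_z - self.coef.T @ self.mean_y


def fit_from_covariances(state: CovarianceState, n_components: int) -> PLSModel:
    """Fit a PLS model from the covariance state alone.

    Implements the modified kernel algorithm #2 on the centered covariance
    pair: per component the weight vector is the dominant left singular vector
    of the current cross-covariance, orthogonalized against previous loadings;
    only the cross-covariance is deflated.  If the requested number of
    components exceeds the informative rank, the model is truncated with a
    warning.
    """
    if n_components < 1:
        raise ValueError("need at least one component")
    cyy, cyz, mu_y, mu_z = state.centered()
    d, m = cyz.shape
    a_max = min(n_components, d)

    r_list, p_list, q_list = [], [], []
    cyz_work = cyz.copy()
    scale = max(float(np.trace(cyy)), 1e-300)
    for _ in range(a_max):
        if m == 1:
            w = cyz_work[:, 0]
        else:
            # dominant left singular vector via the small M x M eigenproblem
            small = cyz_work.T @ cyz_work
            vals, vecs = np.linalg.eigh(small)
            w = cyz_work @ vecs[:, -1]
        nw = np.linalg.norm(w)
        if nw <= 1e-14 * scale:
            break
        w = w / nw
        r = w.copy()
        for p_prev, r_prev in zip(p_list, r_list):
            r = r - (p_prev @ w) * r_prev
        tt = float(r @ cyy @ r)
        if tt <= 1e-13 * scale:
            break
        p = (cyy @ r) / tt
        q = (cyz_work.T @ r) / tt
        cyz_work = cyz_work - tt * np.outer(p, q)
        r_list.append(r)
        p_list.append(p)
        q_list.append(q)

    if not r_list:
        raise ValueError("covariance state has no informative directions")
    if len(r_list) < n_components:
        warnings.warn(
            f"requested {n_components} components but data supports only "
            f"{len(r_list)}; model truncated",
            RuntimeWarning,
        )
    r_mat = np.column_stack(r_list)        # (D, A)
    q_mat = np.column_stack(q_list)        # (M, A)
    p_mat = np.column_stack(p_list)        # (D, A)
    coef = r_mat @ q_mat.T                 # (D, M)
    return PLSModel(
        weights=r_mat.T,
        loadings=p_mat,
        y_loadings=q_mat,
        coef=coef,
        mean_y=mu_y,
        mean_z=mu_z,
        n_components=r_mat.shape[1],
        lam=state.lam,
    )


def predict(model: PLSModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(Z_hat, E)``: predictions (M, T) and latent scores (A, T)."""
    y = np.atleast_2d(np.asarray(features, dtype=float))
    if y.shape[0] != model.mean_y.shape[0]:
        raise ValueError("feature dimension does not match the model")
    yc = y - model.mean_y[:, None]
    z_hat = model.coef.T @ yc + model.mean_z[:, None]
    scores = model.weights @ yc
    return z_hat, scores


def knee_point(curve: np.ndarray) -> int:
    """Knee of a performance-vs-components curve (1-based component count).

    The knee is the point with maximal perpendicular distance to the chord
    joining the curve endpoints (Kneedle-style); ties resolve to the smallest
    component count, so a strictly linear (or constant) curve returns 1.
    """
    curve = np.asarray(curve, dtype=float)
    n = curve.size
    if n == 1:
        return 1
    x = np.arange(1, n + 1, dtype=float)
    x0, y0, x1, y1 = x[0], curve[0], x[-1], curve[-1]
    chord = np.hypot(x1 - x0, y1 - y0)
    if chord == 0:
        return 1
    dist = np.abs((y1 - y0) * x - (x1 - x0) * curve + x1 * y0 - y1 * x0) / chord
    scale = max(float(np.ptp(curve)), 1e-12)
    if dist.max() <= 1e-9 * scale:
        return 1  # straight line: no knee, smallest-A tie-break
    best = int(np.argmax(dist >= dist.max() * (1.0 - 1e-9)))
    return best + 1


def _contiguous_folds(n: int, n_folds: int) -> list[np.ndarray]:
    bounds = np.linspace(0, n, n_folds + 1).astype(int)
    return [np.arange(bounds[k], bounds[k + 1]) for k in range(n_folds)]


def select_components(
    features: np.ndarray,
    targets: np.ndarray,
    a_max: int = 50,
    n_folds: int = 10,
    n_linear: int = 4,
) -> tuple[int, np.ndarray]:
    """Cross-validated knee-point selection of the PLS component count.

    Builds the curve of mean Pearson correlation of the first ``n_linear``
    predicted kinematics (the 4 linear kinematics) against the number of
    components ``A = 1..a_max``, averaged over ``n_folds`` contiguous
    cross-validation folds, and returns ``(A*, curve)`` where ``A*`` is the
    knee of the curve.
    """
    if a_max < 2:
        raise ValueError("a_max must be at least 2")
    y = np.atleast_2d(np.asarray(features, dtype=float))
    z = np.atleast_2d(np.asarray(targets, dtype=float))
    d, n = y.shape
    if n < n_folds:
        raise ValueError("not enough samples for the requested folds")
    a_eff = min(a_max, d)
    k_lin = min(n_linear, z.shape[0])

    folds = _contiguous_folds(n, n_folds)
    curves = np.full((len(folds), a_eff), np.nan)
    for f_idx, val_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[val_idx] = False
        state = CovarianceState.initial(d, z.shape[0], lam=1.0)
        update_covariances(state, y[:, train_mask], z[:, train_mask])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                model = fit_from_covariances(state, a_eff)
        except ValueError:
            curves[f_idx] = 0.0  # nothing informative in this fold
            continue
        yc = y[:, val_idx] - model.mean_y[:, None]
        scores = model.weights @ yc                      # (A_fit, n_val)
        z_val = z[:k_lin, val_idx]
        z_hat = np.tile(model.mean_z[:k_lin, None], (1, val_idx.size))
        for a in range(model.n_components):
            z_hat = z_hat + np.outer(model.y_loadings[:k_lin, a], scores[a])
            curves[f_idx, a] = _mean_safe_corr(z_val, z_hat)
        # rank-truncated fits: carry the last available value forward
        if model.n_components < a_eff:
            curves[f_idx, model.n_components:] = curves[f_idx, model.n_components - 1]

    curve = np.nanmean(curves, axis=0)
    if np.allclose(curve, curve[0], atol=1e-12):
        warnings.warn("degenerate (constant) CV curve; selecting A = 1", RuntimeWarning)
        return 1, curve
    return knee_point(curve), curve


def _mean_safe_corr(z_true: np.ndarray, z_hat: np.ndarray) -> float:
    """Mean Pearson correlation over rows, treating degenerate rows as 0."""
    vals = []
    for a, b in zip(z_true, z_hat):
        sa, sb = a.std(), b.std()
        if sa <= 0 or sb <= 0:
            vals.append(0.0)
        else:
            vals.append(float(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(vals))
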