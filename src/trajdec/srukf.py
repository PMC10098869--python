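"""Square-root unscented Kalman filter cascaded on PLS latent features.

The filter state is the 6-dimensional extended kinematics
``(p_hor, v_hor, p_ver, v_ver, d, s)``.  Both models are learned from the
training pair ``(E, Z)``: a first-order autoregressive transition
``z_t = F z_{t-1} + c + w`` and a linear observation ``e_t = H z_t + b + v``,
with noise covariances taken from the regression residuals.  The filter
propagates a lower-triangular Cholesky factor ``S`` of the state covariance
(``P = S S'``); the full covariance is never formed.

Rank-one factor updates with possibly negative weight (the 0-th sigma-point
term) and the multi-column measurement downdate are carried out by whitening
against the current factor and re-triangularizing a 6x6 matrix through one
Cholesky + QR — algebraically the classic ``cholupdate`` cascade, but without
a per-column scalar loop.  A losing-definiteness downdate falls back to an
eigenvalue-clamped re-factorization with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky
from scipy.linalg.lapack import dgeqrf, dpotrf, dtrtrs

__all__ = ["UKFModel", "fit_ukf_models", "run_srukf"]

STATE_DIM = 6


@dataclass
class UKFModel:
    f_tr: np.ndarray        # (6, 6) transition matrix
    f_offset: np.ndarray    # (6,)
    q_pr: np.ndarray        # (6, 6) process noise
    h_obs: np.ndarray       # (A, 6) observation matrix
    h_offset: np.ndarray    # (A,)
    r_m: np.ndarray         # (A, A) measurement noise
    init_state: np.ndarray  # (6,)
    init_cov: np.ndarray    # (6, 6)
    alpha_s: float = 1e-3
    beta_s: float = 2.0
    kappa_s: float = 0.0

    @property
    def obs_dim(self) -> int:
        return self.h_obs.shape[0]


def _ridge_lstsq(x: np.ndarray, y: np.ndarray, label: str) -> tuple[np.ndarray, np.ndarray]:
    """Least squares of y on [x; 1] with a ridge fallback for rank-deficient
    regressors.  x is (d, n), y is (m, n); returns (coef (m, d), offset (m,))."""
    d, n = x.shape
    design = np.vstack([x, np.ones((1, n))])
    gram = design @ design.T
    rhs = design @ y.T
    rank = np.linalg.matrix_rank(gram, hermitian=True)
    if rank < d + 1:
        warnings.warn(
            f"rank-deficient regressors while fitting the {label} model; "
            "falling back to a ridge solution",
            RuntimeWarning,
        )
        gram = gram + 1e-8 * np.trace(gram) / (d + 1) * np.eye(d + 1)
    sol = np.linalg.solve(gram, rhs).T          # (m, d+1)
    return sol[:, :d], sol[:, d]


def _loaded_cov(resid: np.ndarray, loading: float = 1e-6) -> np.ndarray:
    n = resid.shape[1]
    cov = (resid @ resid.T) / n
    dim = cov.shape[0]
    return cov + max(loading * np.trace(cov) / dim, 1e-12) * np.eye(dim)


def fit_ukf_models(
    latents: np.ndarray,
    kinematics: np.ndarray,
    alpha_s: float = 1e-3,
    beta_s: float = 2.0,
    kappa_s: float = 0.0,
    q_scale: float = 10.0,
) -> UKFModel:
    """Fit transition and observation models from a paired training sequence.

    ``latents`` is the (A, T) PLS latent series E and ``kinematics`` the (6, T)
    extended kinematics Z aligned with it.

    ``q_scale`` inflates the fitted process-noise covariance.  The latent
    observation noise is strongly autocorrelated (the features are band-limited
    below a few Hz) while the filter assumes white measurement noise; with the
    raw residual covariances the filter over-smooths and introduces phase lag.
    Inflating Q restores the balance; at the default the cascade preserves the
    raw decoder's correlation on clean data and improves it on noisy data.
    """
    e = np.atleast_2d(np.asarray(latents, dtype=float))
    z = np.atleast_2d(np.asarray(kinematics, dtype=float))
    if e.shape[1] != z.shape[1]:
        raise ValueError("latent and kinematic sequences must be paired")
    if e.shape[1] < 100:
        raise ValueError("need at least 100 paired samples to fit the filter models")
    if z.shape[0] != STATE_DIM:
        raise ValueError(f"kinematics must have {STATE_DIM} rows (extended kinematics)")

    h_obs, h_off = _ridge_lstsq(z, e, "observation")
    r_m = _loaded_cov(e - h_obs @ z - h_off[:, None])

    if q_scale <= 0:
        raise ValueError("q_scale must be positive")
    f_tr, f_off = _ridge_lstsq(z[:, :-1], z[:, 1:], "transition")
    q_pr = q_scale * _loaded_cov(z[:, 1:] - f_tr @ z[:, :-1] - f_off[:, None])

    return UKFModel(
        f_tr=f_tr,
        f_offset=f_off,
        q_pr=q_pr,
        h_obs=h_obs,
        h_offset=h_off,
        r_m=r_m,
        init_state=z.mean(axis=1),
        init_cov=np.cov(z) + 1e-9 * np.trace(np.cov(z)) / STATE_DIM * np.eye(STATE_DIM),
        alpha_s=alpha_s,
        beta_s=beta_s,
        kappa_s=kappa_s,
    )


def _tri_from(m: np.ndarray) -> np.ndarray:
    """Lower-triangular factor S with S S' = M M' via QR of M'."""
    k = m.shape[0]
    qr_fac, _, _, info = dgeqrf(np.asfortranarray(m.T))
    if info != 0:
        raise np.linalg.LinAlgError("QR factorization failed")
    s = np.triu(qr_fac[:k]).T
    # fix signs so the diagonal is non-negative (canonical factor)
    signs = np.sign(np.diag(s))
    signs[signs == 0] = 1.0
    return s * signs[None, :]


class _FactorUpdater:
    """Rank-k update/downdate of a triangular factor, with PD fallback."""

    def __init__(self) -> None:
        self.fallbacks = 0

    def apply(self, s: np.ndarray, u: np.ndarray, weight: float) -> np.ndarray:
        """Return a factor of S S' + weight * U U' (U may have several columns)."""
        if u.ndim == 1:
            u = u[:, None]
        v, info = dtrtrs(s, u, lower=1)             # whitened columns
        if info != 0:
            raise np.linalg.LinAlgError("singular square-root factor")
        mid = np.eye(s.shape[0]) + weight * (v @ v.T)
        lm_raw, info = dpotrf(mid, lower=1)
        lm = np.tril(lm_raw) if info == 0 else None
        if lm is None:
            # lost positive definiteness: clamp eigenvalues and re-factorize
            self.fallbacks += 1
            vals, vecs = np.linalg.eigh(0.5 * (mid + mid.T))
            vals = np.maximum(vals, 1e-12)
            lm = vecs * np.sqrt(vals)
        return _tri_from(s @ lm)


def run_srukf(model: UKFModel, latents: np.ndarray) -> np.ndarray:
    """Filter a latent sequence into kinematic trajectories.

    Returns the (6, T) filtered extended kinematics; distance and speed are
    recomputed from the filtered positions and velocities so the output is
    internally consistent.  The filter is deterministic.
    """
    e_seq = np.atleast_2d(np.asarray(latents, dtype=float))
    if e_seq.shape[0] != model.obs_dim:
        raise ValueError("latent dimension does not match the observation model")
    n_steps = e_seq.shape[1]
    if n_steps < 1:
        raise ValueError("empty latent sequence")

    n = STATE_DIM
    lam_u = model.alpha_s**2 * (n + model.kappa_s) - n
    gamma = np.sqrt(n + lam_u)
    wm = np.full(2 * n + 1, 1.0 / (2.0 * (n + lam_u)))
    wm[0] = lam_u / (n + lam_u)
    wc = wm.copy()
    wc[0] += 1.0 - model.alpha_s**2 + model.beta_s
    sqrt_wc1 = np.sqrt(wc[1])

    s_q = cholesky(model.q_pr, lower=True)
    s_r = cholesky(model.r_m, lower=True)
    upd = _FactorUpdater()

    x = model.init_state.copy()
    s = cholesky(
        model.init_cov + 1e-12 * np.trace(model.init_cov) * np.eye(n), lower=True
    )
    out = np.empty((n, n_steps))

    f, c = model.f_tr, model.f_offset
    h, b = model.h_obs, model.h_offset

    for t in range(n_steps):
        # --- time update -------------------------------------------------
        gs = gamma * s
        sig = np.concatenate([x[:, None], x[:, None] + gs, x[:, None] - gs], axis=1)
        sig_p = f @ sig + c[:, None]
        x_pred = sig_p @ wm
        dev = sig_p - x_pred[:, None]
        s_pred = _tri_from(np.hstack([sqrt_wc1 * dev[:, 1:], s_q]))
        s_pred = upd.apply(s_pred, dev[:, :1], wc[0])

        # --- measurement update ------------------------------------------
        gs = gamma * s_pred
        sig2 = np.concatenate(
            [x_pred[:, None], x_pred[:, None] + gs, x_pred[:, None] - gs], axis=1
        )
        sig_y = h @ sig2 + b[:, None]
        y_pred = sig_y @ wm
        dev_y = sig_y - y_pred[:, None]
        s_yy = _tri_from(np.hstack([sqrt_wc1 * dev_y[:, 1:], s_r]))
        s_yy = upd.apply(s_yy, dev_y[:, :1], wc[0])
        dev_x = sig2 - x_pred[:, None]
        p_xy = (dev_x * wc[None, :]) @ dev_y.T
        # K = P_xy (S_yy S_yy')^-1 via two triangular solves
        tmp, _ = dtrtrs(s_yy, p_xy.T, lower=1)
        k_gain, _ = dtrtrs(s_yy, tmp, lower=1, trans=1)
        k_gain = k_gain.T
        x = x_pred + k_gain @ (e_seq[:, t] - y_pred)
        s = upd.apply(s_pred, k_gain @ s_yy, -1.0)
        out[:, t] = x

    if upd.fallbacks:
        warnings.warn(
            f"square-root factor lost definiteness {upd.fallbacks} time(s); "
            "re-factorized with clamped eigenvalues",
            RuntimeWarning,
        )
    # recompute the non-linear kinematics from the filtered linear ones
    out[4] = np.hypot(out[0], out[2])
    out[5] = np.hypot(out[1], out[3])
    return out
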