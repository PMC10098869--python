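"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: the PLS oracle is a
plain NIPALS iteration on raw (centered) data with explicit X deflation, and
the Kalman oracle propagates the full covariance.
"""

from __future__ import annotations

import numpy as np


def nipals_pls(x: np.ndarray, y: np.ndarray, n_components: int,
               tol: float = 1e-13, max_iter: int = 2000):
    """Batch two-block PLS (PLS2) by NIPALS on raw data.

    x: (n, d) samples-by-features, y: (n, m).  Returns (coef, mean_x, mean_y)
    with predictions ``(x - mean_x) @ coef + mean_y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mean_x = x.mean(axis=0)
    mean_y = y.mean(axis=0)
    xc = x - mean_x
    yc = y - mean_y
    n, d = xc.shape
    m = yc.shape[1]
    w_list, p_list, q_list = [], [], []
    for _ in range(n_components):
        u = yc[:, [np.argmax(np.sum(yc**2, axis=0))]]
        w = np.zeros((d, 1))
        for _ in range(max_iter):
            w_new = xc.T @ u
            w_new /= np.linalg.norm(w_new)
            t = xc @ w_new
            q = yc.T @ t / (t.T @ t)
            u_new = yc @ q / (q.T @ q)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u = w_new, u_new
        t = xc @ w
        tt = float((t.T @ t).item())
        p = xc.T @ t / tt
        q = yc.T @ t / tt
        xc = xc - t @ p.T
        yc = yc - t @ q.T
        w_list.append(w[:, 0])
        p_list.append(p[:, 0])
        q_list.append(q[:, 0])
    w_mat = np.column_stack(w_list)
    p_mat = np.column_stack(p_list)
    q_mat = np.column_stack(q_list)
    # coefficients: B = W (P'W)^-1 Q'
    coef = w_mat @ np.linalg.solve(p_mat.T @ w_mat, q_mat.T)
    return coef, mean_x, mean_y


def kalman_filter(f, c, q, h, b, r, x0, p0, observations):
    """Conventional linear Kalman filter maintaining the full covariance.

    observations: (m, T).  Returns the filtered state trajectory (n, T).
    """
    x = np.asarray(x0, dtype=float).copy()
    p = np.asarray(p0, dtype=float).copy()
    n = x.size
    t_steps = observations.shape[1]
    out = np.empty((n, t_steps))
    for t in range(t_steps):
        x = f @ x + c
        p = f @ p @ f.T + q
        s = h @ p @ h.T + r
        k = p @ h.T @ np.linalg.inv(s)
        x = x + k @ (observations[:, t] - h @ x - b)
        p = p - k @ h @ p
        out[:, t] = x
    return out
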