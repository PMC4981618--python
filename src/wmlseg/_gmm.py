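"""Small shared 1D Gaussian-mixture / k-means helpers.

Used by the tissue classifier and the bias-field estimator.  Deterministic:
no randomness beyond the caller-supplied initial centers.
"""
from __future__ import annotations

import numpy as np

__all__ = ["kmeans_1d", "fit_gmm_1d", "gmm_log_resp"]


def kmeans_1d(x: np.ndarray, init_centers, max_iter: int = 100) -> np.ndarray:
    """Lloyd iterations on scalar data; empty clusters keep their center."""
    c = np.asarray(init_centers, dtype=float).copy()
    for _ in range(max_iter):
        assign = np.argmin(np.abs(x[:, None] - c[None, :]), axis=1)
        new = c.copy()
        for k in range(c.size):
            sel = assign == k
            if sel.any():
                new[k] = x[sel].mean()
        if np.array_equal(new, c):
            break
        c = new
    return np.sort(c)


def gmm_log_resp(x, means, variances, weights):
    """Log joint densities (n, k) and per-sample log evidence (n,)."""
    logp = (
        -0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
        - 0.5 * np.log(2.0 * np.pi * variances[None, :])
        + np.log(weights[None, :])
    )
    m = logp.max(axis=1, keepdims=True)
    lse = m + np.log(np.exp(logp - m).sum(axis=1, keepdims=True))
    return logp, lse[:, 0]


def fit_gmm_1d(
    x: np.ndarray,
    init_means,
    max_iter: int = 100,
    tol: float = 1e-5,
):
    """Fit a k-component 1D Gaussian mixture by EM.

    Variances are floored at a tiny fraction of the data variance so that
    noiseless (piecewise-constant) inputs stay numerically well-posed.

    Returns (means, variances, weights, converged).
    """
    x = np.asarray(x, dtype=float).ravel()
    means = np.asarray(init_means, dtype=float).copy()
    k = means.size
    var0 = x.var()
    var_floor = max(var0 * 1e-8, 1e-12)
    variances = np.full(k, max(var0 / max(k * k, 1), var_floor))
    weights = np.full(k, 1.0 / k)

    prev_ll = -np.inf
    converged = False
    for it in range(max_iter):
        logp, lse = gmm_log_resp(x, means, variances, weights)
        ll = lse.mean()
        resp = np.exp(logp - lse[:, None])
        nk = resp.sum(axis=0) + 1e-300
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, var_floor)
        if it > 0 and abs(ll - prev_ll) <= tol * max(abs(prev_ll), 1e-12):
            converged = True
            break
        prev_ll = ll
    return means, variances, weights, converged
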