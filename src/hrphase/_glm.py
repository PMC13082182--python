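"""Minimal IRLS fitters used inside bootstrap loops.

Only point estimates are needed per bootstrap replicate, so these skip
the covariance machinery of the full statsmodels fits (which remain the
headline estimators).  Agreement with statsmodels is unit-tested.
"""
from __future__ import annotations

import numpy as np

_MAX_EXP = 30.0


def ols_beta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def logit_beta(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
               tol: float = 1e-10) -> tuple[np.ndarray, bool]:
    """Newton-Raphson (IRLS) logistic regression point estimate.

    Returns (beta, converged).  Diverging fits (separation) are
    reported as non-converged.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_MAX_EXP, _MAX_EXP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        # guard against zero weights under separation
        w = np.maximum(w, 1e-12)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        except np.linalg.LinAlgError:
            return beta, False
        if not np.all(np.isfinite(beta_new)):
            return beta, False
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            return beta, True
        if np.max(np.abs(beta)) > 1e4:
            return beta, False
    return beta, False
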