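"""Memory-lean Newton-Raphson logistic regression.

The weight and first-stage models run on person-period tables with around
a million rows; a general-purpose GLM implementation allocates several
row-length working copies per iteration, which dominates the pipeline's
memory footprint at full scale. This solver keeps only the design matrix
and a handful of row vectors alive: the per-iteration peak is one ``n x k``
temporary for the weighted cross-product.

The optimum is the same unique binomial MLE a standard IRLS/GLM routine
finds; standard errors come from the inverse observed information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit


class LogisticError(ValueError):
    """Raised when the logistic likelihood cannot be maximized."""


@dataclass
class LogisticFit:
    params: np.ndarray
    bse: np.ndarray
    converged: bool
    n_iterations: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(X @ self.params)


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed overflow-safely
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-8,
    max_iterations: int = 100,
) -> LogisticFit:
    """Maximize the Bernoulli likelihood by Newton's method with halving."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if len(y) != n:
        raise LogisticError("response and design lengths differ")
    beta = np.zeros(k)
    # intercept warm start when the first column is constant
    if np.ptp(X[:, 0]) == 0.0 and 0.0 < y.mean() < 1.0:
        beta[0] = np.log(y.mean() / (1.0 - y.mean())) / X[0, 0]
    eta = X @ beta
    ll = _loglik(y, eta)
    converged = False
    n_iter = 0
    H = np.eye(k)
    for n_iter in range(1, max_iterations + 1):
        p = expit(eta)
        grad = X.T @ (y - p)
        w = p * (1.0 - p)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise LogisticError(f"singular information matrix: {exc}") from exc
        new_eta = eta + X @ step
        new_ll = _loglik(y, new_eta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            halvings += 1
            new_eta = eta + X @ step
            new_ll = _loglik(y, new_eta)
        beta = beta + step
        rel_change = abs(new_ll - ll) / max(abs(ll), 1.0)
        eta, ll = new_eta, new_ll
        if np.abs(grad).max() < tol or rel_change < 1e-13:
            converged = True
            break
    p = expit(eta)
    w = p * (1.0 - p)
    H = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(H)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        bse = np.full(k, np.nan)
    return LogisticFit(params=beta, bse=bse, converged=converged, n_iterations=n_iter)
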