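"""Counting-process Cox partial likelihood with weights and clustered errors.

This is the estimation core shared by the crude, covariate-adjusted,
weighted (marginal structural) and control-function analyses: rows are
``[start, stop)`` intervals with time-varying covariates, optional
observation weights and an optional cluster identifier. Ties are handled by
the Efron approximation by default (the 92-day grid produces heavy ties);
Breslow is available. Optimization is Newton's method with step-halving.

The robust variance is the clustered sandwich ``A^-1 B A^-1`` with ``A`` the
observed information and ``B`` the sum over clusters of outer products of
cluster-summed score residuals; with every row its own cluster it reduces to
the standard (Lin-Wei) sandwich.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEPARATION_BOUND = 10.0


class EstimationError(ValueError):
    """Raised when a model cannot be estimated from the given data."""


@dataclass
class CoxSpec:
    covariates: list[str]
    ties: str = "efron"
    weight_col: str | None = None
    cluster_col: str | None = None
    tolerance: float = 1e-8
    max_iterations: int = 50

    def __post_init__(self) -> None:
        if self.ties not in ("efron", "breslow"):
            raise ValueError(f"ties must be 'efron' or 'breslow', got {self.ties!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class CoxFit:
    covariates: list[str]
    coefficients: np.ndarray
    vcov_model: np.ndarray
    loglik: float
    n_events: int
    converged: bool
    n_iterations: int
    separation: bool = False
    vcov_robust: np.ndarray | None = None
    n_clusters: int | None = None
    spec: CoxSpec | None = None
    loglik_null: float = field(default=float("nan"))

    @property
    def model_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_model))

    @property
    def robust_se(self) -> np.ndarray | None:
        if self.vcov_robust is None:
            return None
        return np.sqrt(np.diag(self.vcov_robust))

    def se(self) -> np.ndarray:
        """Robust SE when a cluster column was given, else model-based."""
        return self.robust_se if self.vcov_robust is not None else self.model_se

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.covariates.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se()[self.covariates.index(name)])

    def summary(self) -> pd.DataFrame:
        z = 1.959963984540054
        se = self.se()
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "coef": self.coefficients,
                "hr": np.exp(self.coefficients),
                "se_model": self.model_se,
                "se_robust": self.robust_se if self.vcov_robust is not None else np.nan,
                "hr_ci_low": np.exp(self.coefficients - z * se),
                "hr_ci_high": np.exp(self.coefficients + z * se),
            }
        )


class _PartialLikelihood:
    """Weighted Efron/Breslow partial likelihood on precomputed risk sets."""

    def __init__(
        self,
        X: np.ndarray,
        w: np.ndarray,
        start: np.ndarray,
        stop: np.ndarray,
        event: np.ndarray,
        ties: str,
    ) -> None:
        self.X, self.w, self.ties = X, w, ties
        times = np.unique(stop[event & (w > 0)])
        self.event_times = times
        self.risk_idx = [np.flatnonzero((start < t) & (stop >= t)) for t in times]
        self.death_idx = [np.flatnonzero(event & (stop == t) & (w > 0)) for t in times]

    def _fracs(self, m: int) -> np.ndarray:
        if self.ties == "efron":
            return np.arange(m) / m
        return np.zeros(m)

    def value_grad_hess(self, beta: np.ndarray):
        X, w = self.X, self.w
        eta = X @ beta
        # guard against overflow in degenerate/separating fits
        r = w * np.exp(np.clip(eta, -500, 500))
        k = X.shape[1]
        ll, U, H = 0.0, np.zeros(k), np.zeros((k, k))
        for R, D in zip(self.risk_idx, self.death_idx):
            rR, XR = r[R], X[R]
            rD, XD = r[D], X[D]
            s0R = rR.sum()
            s1R = rR @ XR
            s2R = XR.T @ (rR[:, None] * XR)
            s0D = rD.sum()
            s1D = rD @ XD
            s2D = XD.T @ (rD[:, None] * XD)
            m = len(D)
            wbar = w[D].sum() / m
            fr = self._fracs(m)
            denom = s0R - fr * s0D
            ll += float(w[D] @ eta[D]) - wbar * float(np.log(denom).sum())
            M = (s1R[None, :] - fr[:, None] * s1D[None, :]) / denom[:, None]
            U += (w[D, None] * XD).sum(axis=0) - wbar * M.sum(axis=0)
            inv = 1.0 / denom
            H += wbar * (s2R * inv.sum() - s2D * (fr * inv).sum() - M.T @ M)
        return ll, U, H

    def score_residuals(self, beta: np.ndarray) -> np.ndarray:
        """Per-row score residuals; columns sum to the total score."""
        X, w = self.X, self.w
        eta = X @ beta
        r = w * np.exp(np.clip(eta, -500, 500))
        n, k = X.shape
        S = np.zeros((n, k))
        for R, D in zip(self.risk_idx, self.death_idx):
            rR, XR = r[R], X[R]
            rD, XD = r[D], X[D]
            s0R, s1R = rR.sum(), rR @ XR
            s0D, s1D = rD.sum(), rD @ XD
            m = len(D)
            wbar = w[D].sum() / m
            fr = self._fracs(m)
            denom = s0R - fr * s0D
            inv = 1.0 / denom
            M = (s1R[None, :] - fr[:, None] * s1D[None, :]) * inv[:, None]
            g_r = wbar * inv.sum()
            k_r = wbar * (inv @ M)
            g_d = wbar * ((1 - fr) * inv).sum()
            k_d = wbar * (((1 - fr) * inv) @ M)
            S[R] -= r[R, None] * (X[R] * g_r - k_r[None, :])
            # event rows: undo the all-risk attribution, apply the event one
            S[D] += r[D, None] * (X[D] * g_r - k_r[None, :])
            S[D] -= r[D, None] * (X[D] * g_d - k_d[None, :])
            S[D] += w[D, None] * (XD - M.mean(axis=0)[None, :])
        return S


def _prepare(df: pd.DataFrame, spec: CoxSpec, start_col, stop_col, event_col):
    for col in [*spec.covariates, start_col, stop_col, event_col]:
        if col not in df.columns:
            raise EstimationError(f"missing column {col!r}")
    X = df[spec.covariates].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise EstimationError("missing values in covariates")
    if spec.weight_col is not None:
        w = df[spec.weight_col].to_numpy(dtype=float)
        if np.isnan(w).any() or (w <= 0).any():
            raise EstimationError("weights must be positive and non-missing")
    else:
        w = np.ones(len(df))
    start = df[start_col].to_numpy(dtype=float)
    stop = df[stop_col].to_numpy(dtype=float)
    if (stop <= start).any():
        raise EstimationError("stop must exceed start for every row")
    event = df[event_col].to_numpy(dtype=bool)
    if not event.any():
        raise EstimationError("no events in the data")
    return X, w, start, stop, event


def fit_cox(
    df: pd.DataFrame,
    spec: CoxSpec,
    start_col: str = "start_day",
    stop_col: str = "stop_day",
    event_col: str = "event",
) -> CoxFit:
    """Maximize the (weighted) partial likelihood; see module docstring."""
    X, w, start, stop, event = _prepare(df, spec, start_col, stop_col, event_col)
    pl = _PartialLikelihood(X, w, start, stop, event, spec.ties)
    k = X.shape[1]
    beta = np.zeros(k)
    ll, U, H = pl.value_grad_hess(beta)
    ll_null = ll
    converged = False
    separation = False
    n_iter = 0
    for n_iter in range(1, spec.max_iterations + 1):
        try:
            step = np.linalg.solve(H, U)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"singular information matrix: {exc}") from exc
        # step-halving on likelihood decrease
        new_beta = beta + step
        new_ll, new_U, new_H = pl.value_grad_hess(new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            halvings += 1
            new_beta = beta + step
            new_ll, new_U, new_H = pl.value_grad_hess(new_beta)
        rel_change = abs(new_ll - ll) / max(abs(ll), 1.0)
        beta, ll, U, H = new_beta, new_ll, new_U, new_H
        if np.abs(beta).max() > SEPARATION_BOUND:
            separation = True
            warnings.warn(
                "diverging coefficient (|beta| > 10): possible complete separation",
                stacklevel=2,
            )
            break
        if np.abs(U).max() < spec.tolerance and rel_change < 1e-10:
            converged = True
            break
    if not converged and not separation:
        warnings.warn("Cox fit did not converge", stacklevel=2)
    vcov = np.linalg.inv(H)
    fit = CoxFit(
        covariates=list(spec.covariates),
        coefficients=beta,
        vcov_model=vcov,
        loglik=float(ll),
        n_events=int(event.sum()),
        converged=converged,
        n_iterations=n_iter,
        separation=separation,
        spec=spec,
        loglik_null=float(ll_null),
    )
    if spec.cluster_col is not None:
        fit.vcov_robust, fit.n_clusters = _robust_vcov(
            pl, beta, H, df[spec.cluster_col].to_numpy()
        )
    return fit


def _robust_vcov(pl: _PartialLikelihood, beta, H, clusters):
    codes, uniq = pd.factorize(clusters)
    if len(uniq) < 2:
        raise EstimationError("cluster-robust variance requires at least 2 clusters")
    S = pl.score_residuals(beta)
    k = S.shape[1]
    cluster_scores = np.zeros((len(uniq), k))
    np.add.at(cluster_scores, codes, S)
    B = cluster_scores.T @ cluster_scores
    Ainv = np.linalg.inv(H)
    return Ainv @ B @ Ainv, len(uniq)


def robust_sandwich(
    fit: CoxFit,
    df: pd.DataFrame,
    cluster_col: str,
    start_col: str = "start_day",
    stop_col: str = "stop_day",
    event_col: str = "event",
) -> np.ndarray:
    """Cluster-robust standard errors for an already-fitted model."""
    if not (fit.converged or fit.separation):
        warnings.warn("computing sandwich variance at a non-converged solution", stacklevel=2)
    assert fit.spec is not None
    X, w, start, stop, event = _prepare(df, fit.spec, start_col, stop_col, event_col)
    pl = _PartialLikelihood(X, w, start, stop, event, fit.spec.ties)
    _, _, H = pl.value_grad_hess(fit.coefficients)
    vcov, n_clusters = _robust_vcov(pl, fit.coefficients, H, df[cluster_col].to_numpy())
    fit.vcov_robust, fit.n_clusters = vcov, n_clusters
    return np.sqrt(np.diag(vcov))
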