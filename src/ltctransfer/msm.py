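"""Marginal structural model: stabilized IPT/IPC weights + weighted Cox.

Treatment and censoring probabilities come from pooled logistic regressions
over person-periods. The stabilized weight for window ``k`` is

    sw_k = [P_num(T_k = t_k) / P_den(T_k = t_k)]
         * [P_num(C_k = 0)  / P_den(C_k = 0)]

where numerator models condition on baseline covariates and exposure
history only and denominator models add the time-varying confounders; the
per-window weights are cumulatively multiplied within resident to carry the
full exposure/confounder history forward. The weighted cause-specific Cox
fit uses the home-level cluster-robust sandwich variance.

Censoring here means loss to follow-up through discharge without
readmission; administrative end of study is non-informative by design and
death is an outcome, never a censoring event in the weight models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import BASELINE_COVARIATES, TIME_VARYING_COVARIATES
from .cox import CoxSpec, EstimationError, fit_cox
from .logistic import LogisticError, fit_logistic
from .results import HazardEstimate, estimate_from_fit

PROB_CLIP = 1e-6
HISTORY_TERMS = ["prev_exposed", "cum_exposed_prior"]


@dataclass
class WeightModelSpec:
    denominator_covariates: list[str] = field(
        default_factory=lambda: BASELINE_COVARIATES + TIME_VARYING_COVARIATES
    )
    numerator_covariates: list[str] = field(default_factory=lambda: list(BASELINE_COVARIATES))
    censoring_covariates: list[str] | None = None  # default: denominator list
    truncation: tuple[float, float] | None = (1.0, 99.0)
    period_terms: bool = True
    history_terms: bool = True

    def __post_init__(self) -> None:
        extra = set(self.numerator_covariates) - set(self.denominator_covariates) - set(
            BASELINE_COVARIATES
        )
        if extra:
            raise ValueError(
                "numerator covariates must be a subset of the denominator set "
                f"plus baseline terms; offending: {sorted(extra)}"
            )


@dataclass
class StabilizedWeightSet:
    """Per-row probabilities and cumulative stabilized weights."""

    table: pd.DataFrame  # resident_id, period_index, p_*, sw_period, sw_cum, truncated

    def diagnostics(self) -> pd.DataFrame:
        """Per-period mean/SD/min/max of the cumulative weight."""
        g = self.table.groupby("period_index")["sw_cum"]
        out = g.agg(["mean", "std", "min", "max", "size"]).reset_index()
        out.columns = ["period_index", "mean", "sd", "min", "max", "n"]
        return out


def _design(pp: pd.DataFrame, covariates: list[str], spec: WeightModelSpec) -> np.ndarray:
    cols = [np.ones(len(pp))]
    names = ["const"]
    for c in covariates:
        cols.append(pp[c].to_numpy(dtype=float))
        names.append(c)
    if spec.period_terms:
        k = pp["period_index"].to_numpy(dtype=float)
        cols += [k, k**2]
        names += ["period", "period2"]
    if spec.history_terms:
        for c in HISTORY_TERMS:
            cols.append(pp[c].to_numpy(dtype=float))
            names.append(c)
    return np.column_stack(cols)


def _pooled_logistic(y: np.ndarray, X: np.ndarray, label: str):
    try:
        res = fit_logistic(y, X)
    except LogisticError as exc:
        raise EstimationError(f"logistic model {label!r} failed: {exc}") from exc
    if not res.converged:
        raise EstimationError(f"logistic model {label!r} did not converge")
    return res


def fit_treatment_models(pp: pd.DataFrame, spec: WeightModelSpec | None = None) -> pd.DataFrame:
    """Fit the four pooled logistic models and attach per-row probabilities.

    Returns a frame aligned with ``pp`` holding the probability assigned to
    the *observed* exposure value (numerator and denominator models) and the
    probability of remaining uncensored, clipped away from {0, 1}.
    """
    spec = spec or WeightModelSpec()
    t = pp["exposed"].to_numpy(dtype=float)
    X_den = _design(pp, spec.denominator_covariates, spec)
    p_den = _pooled_logistic(t, X_den, "treatment denominator").predict(X_den)
    X_num = _design(pp, spec.numerator_covariates, spec)
    p_num = _pooled_logistic(t, X_num, "treatment numerator").predict(X_num)

    cens = (pp["censor_reason"] == "discharge").to_numpy(dtype=float)
    cens_covs = spec.censoring_covariates or spec.denominator_covariates
    if cens.sum() == 0:
        p_unc_den = np.ones(len(pp))
        p_unc_num = np.ones(len(pp))
    else:
        X_cens = (
            X_den if cens_covs is spec.denominator_covariates
            else _design(pp, cens_covs, spec)
        )
        p_unc_den = 1.0 - _pooled_logistic(cens, X_cens, "censoring denominator").predict(X_cens)
        p_unc_num = 1.0 - _pooled_logistic(cens, X_num, "censoring numerator").predict(X_num)

    def observed(p: np.ndarray) -> np.ndarray:
        return np.where(t > 0, p, 1.0 - p)

    out = pd.DataFrame(
        {
            "resident_id": pp["resident_id"].to_numpy(),
            "period_index": pp["period_index"].to_numpy(),
            "p_num_treat": np.clip(observed(p_num), PROB_CLIP, 1 - PROB_CLIP),
            "p_den_treat": np.clip(observed(p_den), PROB_CLIP, 1 - PROB_CLIP),
            # an uncensored probability of exactly 1 is legitimate (no
            # censoring in the data), so only the lower side is clipped
            "p_num_cens": np.clip(p_unc_num, PROB_CLIP, 1.0),
            "p_den_cens": np.clip(p_unc_den, PROB_CLIP, 1.0),
        },
        index=pp.index,
    )
    return out


def compute_stabilized_weights(
    probs: pd.DataFrame, truncation: tuple[float, float] | None = (1.0, 99.0)
) -> StabilizedWeightSet:
    """Per-window stabilized weights and their within-resident running product."""
    for col in ("p_num_treat", "p_den_treat", "p_num_cens", "p_den_cens"):
        vals = probs[col].to_numpy(dtype=float)
        if (vals <= 0).any() or np.isnan(vals).any():
            raise ValueError(f"nonpositive or missing probability in {col!r}")
    tab = probs.copy()
    tab["sw_period"] = (tab["p_num_treat"] / tab["p_den_treat"]) * (
        tab["p_num_cens"] / tab["p_den_cens"]
    )
    tab = tab.sort_values(["resident_id", "period_index"], kind="mergesort")
    tab["sw_cum"] = tab.groupby("resident_id")["sw_period"].cumprod()
    tab["truncated"] = 0
    if truncation is not None:
        lo_p, hi_p = truncation
        lo, hi = np.percentile(tab["sw_cum"], [lo_p, hi_p])
        clipped = (tab["sw_cum"] < lo) | (tab["sw_cum"] > hi)
        tab["truncated"] = clipped.astype(int)
        tab["sw_cum"] = tab["sw_cum"].clip(lo, hi)
    return StabilizedWeightSet(table=tab.sort_index())


def estimate_weights(
    pp: pd.DataFrame, spec: WeightModelSpec | None = None
) -> StabilizedWeightSet:
    """Convenience: treatment/censoring models + stabilized weights."""
    spec = spec or WeightModelSpec()
    probs = fit_treatment_models(pp, spec)
    return compute_stabilized_weights(probs, spec.truncation)


def fit_msm(
    pp: pd.DataFrame,
    weights: StabilizedWeightSet,
    outcome: str,
    spec: WeightModelSpec | None = None,
    cluster_col: str = "home_id",
) -> HazardEstimate:
    """Weighted cause-specific Cox of the outcome on exposure.

    Covariates are the exposure plus the numerator (baseline) covariate set;
    weights are the cumulative stabilized weights; variance is the
    cluster-robust sandwich at the home level.
    """
    spec = spec or WeightModelSpec()
    df = pp.copy()
    df["_sw"] = weights.table.loc[df.index, "sw_cum"]
    covs = ["exposed"] + list(spec.numerator_covariates)
    fit = fit_cox(
        df,
        CoxSpec(covariates=covs, weight_col="_sw", cluster_col=cluster_col),
    )
    est = estimate_from_fit(fit, "msm", outcome)
    est.extra["mean_weight"] = float(df["_sw"].mean())
    return est


def fit_extended_cox(
    pp: pd.DataFrame,
    outcome: str,
    covariates: list[str] | None = None,
    cluster_col: str = "home_id",
) -> HazardEstimate:
    """Unweighted extended Cox adjusting directly for time-varying confounders."""
    covs = ["exposed"] + (
        covariates
        if covariates is not None
        else BASELINE_COVARIATES + TIME_VARYING_COVARIATES
    )
    fit = fit_cox(pp, CoxSpec(covariates=covs, cluster_col=cluster_col))
    return estimate_from_fit(fit, "extended_cox", outcome)


def fit_crude_cox(
    pp: pd.DataFrame, outcome: str, cluster_col: str = "home_id"
) -> HazardEstimate:
    """Cox of the outcome on the time-varying exposure alone."""
    fit = fit_cox(pp, CoxSpec(covariates=["exposed"], cluster_col=cluster_col))
    return estimate_from_fit(fit, "crude", outcome)
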