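"""Preference-based instrumental-variable analysis via a control function.

The instrument ``z`` is the proportion of a home's residents transferred to
hospital in the previous year — a provider-practice-variation ("preference")
instrument. Estimation is two-stage residual inclusion (2SRI): a logistic
first stage of exposure on ``z`` and baseline covariates, whose per-row
residual enters the Cox outcome model as a control function absorbing
unmeasured confounding shared by exposure and outcome. The exposure
coefficient is a causal log hazard ratio for residents whose transfer is
sensitive to the instrument (a complier-type estimand).

Diagnostics cover the three instrument assumptions: relevance (first-stage
Wald statistic), exogeneity proxy (baseline covariate balance across
instrument quintiles) and an outcome-incidence-by-quintile table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import BASELINE_COVARIATES
from .cox import CoxSpec, EstimationError, fit_cox
from .logistic import fit_logistic
from .incidence import standardized_mean_difference
from .results import HazardEstimate, estimate_from_fit

PERIODS_PER_YEAR = 4


class WeakInstrumentWarning(UserWarning):
    pass


@dataclass
class FirstStageResult:
    params: dict[str, float]
    fitted: pd.Series  # P(exposed = 1 | z, covariates), aligned with input
    residuals: pd.Series  # observed exposure minus fitted
    wald_z: float
    weak: bool
    separation: bool = False


@dataclass
class IVFit:
    estimate: HazardEstimate
    stage1: FirstStageResult
    residual_coef: float
    residual_se: float
    ci_method: str
    n_boot: int = 0
    boot_failures: int = 0
    boot_estimates: np.ndarray | None = None


def compute_instrument(
    cohort: pd.DataFrame, home_history: pd.DataFrame
) -> pd.DataFrame:
    """Per home-year transfer proportion with denominator counts.

    Year ``y`` of follow-up uses transfers observed in year ``y - 1``
    (periods ``4(y-1) .. 4y - 1``); the first follow-up year uses the
    burn-in history block supplied with the synthetic data. A home-year
    with no prior-year residents gets a missing ``z``.
    """
    max_year = int(cohort["period_index"].max()) // PERIODS_PER_YEAR
    rows = []
    for _, h in home_history.iterrows():
        n, k = int(h["n_residents_prior_year"]), int(h["n_transferred_prior_year"])
        rows.append(
            {
                "home_id": h["home_id"],
                "year": 0,
                "n_residents_prior_year": n,
                "n_transferred_prior_year": k,
                "z": k / n if n > 0 else np.nan,
            }
        )
    cohort = cohort[["home_id", "resident_id", "period_index", "transfer"]]
    for year in range(1, max_year + 1):
        lo = (year - 1) * PERIODS_PER_YEAR
        hi = year * PERIODS_PER_YEAR
        prior = cohort[(cohort["period_index"] >= lo) & (cohort["period_index"] < hi)]
        g = prior.groupby(["home_id", "resident_id"])["transfer"].max().reset_index()
        agg = g.groupby("home_id")["transfer"].agg(["size", "sum"])
        for home_id in home_history["home_id"]:
            if home_id in agg.index:
                n = int(agg.loc[home_id, "size"])
                k = int(agg.loc[home_id, "sum"])
            else:
                n, k = 0, 0
            rows.append(
                {
                    "home_id": home_id,
                    "year": year,
                    "n_residents_prior_year": n,
                    "n_transferred_prior_year": k,
                    "z": k / n if n > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def attach_instrument(
    pp: pd.DataFrame, instrument: pd.DataFrame, fixed_at_admission: bool = False
) -> pd.DataFrame:
    """Join each person-period row to its home's current instrument value.

    Rows whose home-year has a missing instrument are excluded with a
    warning reporting the count. With ``fixed_at_admission`` every row uses
    the home's year-0 value.
    """
    df = pp.copy()
    if fixed_at_admission:
        z0 = instrument[instrument["year"] == 0].set_index("home_id")["z"]
        df["z"] = df["home_id"].map(z0)
    else:
        df["year"] = df["period_index"] // PERIODS_PER_YEAR
        df = df.merge(instrument[["home_id", "year", "z"]], on=["home_id", "year"], how="left")
        df = df.drop(columns=["year"])
    n_missing = int(df["z"].isna().sum())
    if n_missing:
        warnings.warn(
            f"excluding {n_missing} person-period rows with missing instrument",
            stacklevel=2,
        )
        df = df[df["z"].notna()]
    return df.reset_index(drop=True)


def first_stage(
    pp_z: pd.DataFrame, covariates: list[str] | None = None
) -> FirstStageResult:
    """Logistic regression of exposure on the instrument + baseline covariates."""
    covariates = covariates if covariates is not None else list(BASELINE_COVARIATES)
    y = pp_z["exposed"].to_numpy(dtype=float)
    z = pp_z["z"].to_numpy(dtype=float)
    if np.ptp(z) == 0.0:
        warnings.warn(
            "instrument is constant across homes; relevance statistic is 0",
            WeakInstrumentWarning,
            stacklevel=2,
        )
        X = np.column_stack([np.ones(len(pp_z))] + [pp_z[c].to_numpy(float) for c in covariates])
        res = fit_logistic(y, X)
        fitted = pd.Series(res.predict(X), index=pp_z.index)
        params = {"const": res.params[0], "z": 0.0}
        params.update({c: res.params[i + 1] for i, c in enumerate(covariates)})
        return FirstStageResult(
            params=params,
            fitted=fitted,
            residuals=pp_z["exposed"] - fitted,
            wald_z=0.0,
            weak=True,
        )
    names = ["const", "z"] + covariates
    X = np.column_stack(
        [np.ones(len(pp_z)), z] + [pp_z[c].to_numpy(float) for c in covariates]
    )
    res = fit_logistic(y, X)
    separation = bool(np.abs(res.params).max() > 15)
    if separation:
        warnings.warn(
            "first-stage coefficients diverge: possible separation between "
            "instrument and exposure",
            stacklevel=2,
        )
    fitted = pd.Series(res.predict(X), index=pp_z.index)
    wald = float(res.params[1] / res.bse[1]) if res.bse[1] > 0 else 0.0
    weak = abs(wald) < 2.0
    if weak:
        warnings.warn(
            f"weak instrument: first-stage Wald z = {wald:.2f}",
            WeakInstrumentWarning,
            stacklevel=2,
        )
    return FirstStageResult(
        params=dict(zip(names, res.params)),
        fitted=fitted,
        residuals=pp_z["exposed"] - fitted,
        wald_z=wald,
        weak=weak,
        separation=separation,
    )


def control_function_cox(
    pp_z: pd.DataFrame,
    stage1: FirstStageResult,
    outcome: str,
    covariates: list[str] | None = None,
    cluster_col: str = "home_id",
    include_residual: bool = True,
    ci_method: str = "cluster_robust",
    n_boot: int = 500,
    seed: int | None = None,
) -> IVFit:
    """Second stage: Cox of the outcome on exposure + first-stage residual.

    With ``include_residual=False`` the fit reduces exactly to the
    covariate-adjusted Cox (useful as a specification check). Confidence
    intervals come from the home-clustered sandwich by default, or from a
    nonparametric cluster bootstrap over homes (``ci_method="bootstrap"``).
    """
    covariates = covariates if covariates is not None else list(BASELINE_COVARIATES)
    df = pp_z.copy()
    df["_cf_resid"] = stage1.residuals
    covs = ["exposed"] + (["_cf_resid"] if include_residual else []) + covariates
    fit = fit_cox(df, CoxSpec(covariates=covs, cluster_col=cluster_col))
    est = estimate_from_fit(fit, "iv", outcome, stage1_wald_z=stage1.wald_z)
    if include_residual:
        i = fit.covariates.index("_cf_resid")
        residual_coef = float(fit.coefficients[i])
        residual_se = float(fit.se()[i])
    else:
        residual_coef, residual_se = 0.0, float("nan")

    boot_estimates = None
    boot_failures = 0
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        homes = pp_z[cluster_col].unique()
        draws = []
        by_home = {h: pp_z[pp_z[cluster_col] == h] for h in homes}
        for _ in range(n_boot):
            picked = rng.choice(homes, size=len(homes), replace=True)
            parts = []
            for j, h in enumerate(picked):
                part = by_home[h].copy()
                part[cluster_col] = f"boot{j}"
                # keep resampled residents distinct for within-resident ops
                part["resident_id"] = part["resident_id"].astype(str) + f"~{j}"
                parts.append(part)
            sample = pd.concat(parts, ignore_index=True)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    s1 = first_stage(sample, covariates=covariates)
                    sample["_cf_resid"] = s1.residuals
                    bf = fit_cox(
                        sample,
                        CoxSpec(covariates=["exposed", "_cf_resid"] + covariates),
                    )
                draws.append(bf.coef("exposed"))
            except (EstimationError, np.linalg.LinAlgError):
                boot_failures += 1
        if len(draws) < max(10, n_boot // 2):
            raise EstimationError(
                f"bootstrap failed in {boot_failures}/{n_boot} resamples"
            )
        boot_estimates = np.asarray(draws)
        lo, hi = np.percentile(boot_estimates, [2.5, 97.5])
        est.ci_low, est.ci_high = float(np.exp(lo)), float(np.exp(hi))
        est.extra["boot_se"] = float(boot_estimates.std(ddof=1))
    elif ci_method != "cluster_robust":
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return IVFit(
        estimate=est,
        stage1=stage1,
        residual_coef=residual_coef,
        residual_se=residual_se,
        ci_method=ci_method,
        n_boot=n_boot if ci_method == "bootstrap" else 0,
        boot_failures=boot_failures,
        boot_estimates=boot_estimates,
    )


def fit_iv(
    pp: pd.DataFrame,
    cohort: pd.DataFrame,
    home_history: pd.DataFrame,
    outcome: str,
    **kwargs,
) -> IVFit:
    """Instrument construction + both stages in one call."""
    instrument = compute_instrument(cohort, home_history)
    pp_z = attach_instrument(pp, instrument)
    s1 = first_stage(pp_z)
    return control_function_cox(pp_z, s1, outcome, **kwargs)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

_DIAG_BASELINE = [
    ("age_at_admission", "continuous"),
    ("sex_female", "proportion"),
    ("adl_hierarchy", "continuous"),
    ("cps", "continuous"),
    ("chess", "continuous"),
    ("comorbidity_burden", "continuous"),
]


def _resident_quintiles(cohort: pd.DataFrame, z0: pd.Series) -> pd.Series:
    """Resident-weighted quintiles of the year-0 instrument (ties by home id)."""
    base = cohort[cohort["period_index"] == 0][["resident_id", "home_id"]].copy()
    base["z"] = base["home_id"].map(z0)
    order = base.sort_values(["z", "home_id", "resident_id"], kind="mergesort")
    ranks = np.arange(len(order))
    q = np.minimum((5 * ranks) // max(len(order), 1), 4) + 1
    return pd.Series(q, index=order["resident_id"].to_numpy()).sort_index()


def instrument_diagnostics(
    cohort: pd.DataFrame, instrument: pd.DataFrame
) -> dict:
    """Relevance, balance-across-quintiles and quintile incidence checks."""
    if instrument["home_id"].nunique() < 2:
        raise ValueError("instrument diagnostics require at least 2 homes")
    z0 = instrument[instrument["year"] == 0].set_index("home_id")["z"]
    df = cohort.copy()
    df["year"] = df["period_index"] // PERIODS_PER_YEAR
    df = df.merge(instrument[["home_id", "year", "z"]], on=["home_id", "year"], how="left")
    df = df[df["z"].notna()]

    # relevance: pooled logistic of the per-period transfer on z
    if np.ptp(df["z"].to_numpy()) == 0.0:
        relevance_wald = 0.0
    else:
        X = np.column_stack([np.ones(len(df)), df["z"].to_numpy(float)])
        res = fit_logistic(df["transfer"].to_numpy(float), X)
        relevance_wald = float(res.params[1] / res.bse[1])

    quint = _resident_quintiles(cohort, z0)
    n_quintiles = int(quint.nunique())
    if n_quintiles < 5:
        warnings.warn(
            f"instrument quintiles collapsed to {n_quintiles} distinct groups",
            stacklevel=2,
        )
    base = cohort[cohort["period_index"] == 0].set_index("resident_id")
    base["quintile"] = quint
    q1 = base[base["quintile"] == 1]
    q5 = base[base["quintile"] == base["quintile"].max()]
    smd_rows = []
    for var, kind in _DIAG_BASELINE:
        if kind == "continuous":
            s = standardized_mean_difference(
                (q1[var].mean(), q1[var].std(ddof=1)),
                (q5[var].mean(), q5[var].std(ddof=1)),
                "continuous",
            ).smd
        else:
            s = standardized_mean_difference(q1[var].mean(), q5[var].mean(), "proportion").smd
        smd_rows.append({"variable": var, "smd_q1_vs_q5": s})

    # crude outcome incidence by quintile (deaths per 100 person-years and
    # ever-transfer proportion, from the assessment table itself)
    coh = cohort.copy()
    coh["quintile"] = coh["resident_id"].map(quint)
    inc_rows = []
    for q, sub in coh.groupby("quintile"):
        py = len(sub) * 92.0 / 365.25
        deaths = int(sub["died_in_period"].sum())
        ever = sub.groupby("resident_id")["transfer"].max().mean()
        inc_rows.append(
            {
                "quintile": int(q),
                "n_residents": int(sub["resident_id"].nunique()),
                "death_rate_per_100py": 100.0 * deaths / py if py > 0 else np.nan,
                "prop_ever_transferred": float(ever),
            }
        )
    return {
        "relevance_wald_z": relevance_wald,
        "baseline_smd": pd.DataFrame(smd_rows),
        "quintile_incidence": pd.DataFrame(inc_rows),
        "n_quintiles": n_quintiles,
    }
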