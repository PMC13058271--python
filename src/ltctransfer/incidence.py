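"""Incidence rates, rate ratios and baseline balance (SMD) tables.

Rates are reported per 100 person-years. Confidence intervals use the
log-rate normal approximation ``rate * exp(+/- 1.96 / sqrt(events))`` when
events >= 5 and the exact Poisson (chi-square) interval for fewer events.
Rate-ratio intervals are normal on the log scale with standard error
``sqrt(1/e1 + 1/e2)``.

Standardized mean differences use the pooled-dispersion (Cohen's-d style)
form and are reported as absolute values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from . import cohort as cohort_mod

Z95 = 1.959963984540054


@dataclass
class IncidenceResult:
    group: str
    events: int
    person_years: float
    rate_per_100py: float
    ci_low: float
    ci_high: float


@dataclass
class RateRatio:
    ratio: float
    ci_low: float | None
    ci_high: float | None


@dataclass
class SMDResult:
    variable: str
    kind: str  # "continuous" | "proportion"
    summary_a: tuple
    summary_b: tuple
    smd: float


def incidence_rate(events: int, person_years: float, group: str = "") -> IncidenceResult:
    """Incidence rate per 100 person-years with a 95% CI."""
    if person_years <= 0:
        raise ValueError(f"person_years must be positive, got {person_years}")
    if events < 0:
        raise ValueError("events must be nonnegative")
    rate = 100.0 * events / person_years
    if events == 0:
        lo = 0.0
        hi = 100.0 * (stats.chi2.ppf(0.975, 2) / 2.0) / person_years
    elif events < 5:  # exact Poisson for sparse counts
        lo = 100.0 * (stats.chi2.ppf(0.025, 2 * events) / 2.0) / person_years
        hi = 100.0 * (stats.chi2.ppf(0.975, 2 * (events + 1)) / 2.0) / person_years
    else:
        half = math.exp(Z95 / math.sqrt(events))
        lo, hi = rate / half, rate * half
    return IncidenceResult(group, int(events), float(person_years), rate, lo, hi)


def rate_ratio(numerator: IncidenceResult, denominator: IncidenceResult) -> RateRatio:
    """Ratio of two incidence rates with a log-scale normal CI."""
    if denominator.rate_per_100py <= 0:
        raise ValueError("denominator rate must be positive")
    ratio = numerator.rate_per_100py / denominator.rate_per_100py
    if numerator.events > 0 and denominator.events > 0:
        se = math.sqrt(1.0 / numerator.events + 1.0 / denominator.events)
        return RateRatio(ratio, ratio * math.exp(-Z95 * se), ratio * math.exp(Z95 * se))
    return RateRatio(ratio, None, None)


def standardized_mean_difference(summary_a, summary_b, kind: str) -> SMDResult:
    """SMD between two group summaries.

    ``kind="continuous"``: summaries are ``(mean, sd)`` pairs and
    ``smd = |m_a - m_b| / sqrt((s_a^2 + s_b^2) / 2)``.
    ``kind="proportion"``: summaries are proportions ``p`` and
    ``smd = |p_a - p_b| / sqrt((p_a(1-p_a) + p_b(1-p_b)) / 2)``.
    """
    if kind == "continuous":
        (ma, sa), (mb, sb) = summary_a, summary_b
        if sa <= 0 or sb <= 0:
            raise ValueError("continuous SMD requires positive dispersions")
        smd = abs(ma - mb) / math.sqrt((sa**2 + sb**2) / 2.0)
        return SMDResult("", kind, (ma, sa), (mb, sb), smd)
    if kind == "proportion":
        pa, pb = float(summary_a), float(summary_b)
        if not (0.0 <= pa <= 1.0 and 0.0 <= pb <= 1.0):
            raise ValueError("proportions must lie in [0, 1]")
        denom = math.sqrt((pa * (1 - pa) + pb * (1 - pb)) / 2.0)
        smd = 0.0 if pa == pb else abs(pa - pb) / denom
        return SMDResult("", kind, (pa,), (pb,), smd)
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# table builders
# ---------------------------------------------------------------------------

def ever_transferred_ids(cohort: pd.DataFrame) -> set:
    """Residents with at least one transfer during follow-up."""
    g = cohort.groupby("resident_id")["transfer"].max()
    return set(g[g > 0].index)


def incidence_table(
    pp_by_outcome: dict[str, pd.DataFrame], cohort: pd.DataFrame
) -> pd.DataFrame:
    """Incidence by ever/never transfer status, one row per outcome.

    Residents (not periods) are classified by ever/never status, matching
    the usual descriptive framing; this classification carries the
    immortal-time caveat discussed in the methods note.
    """
    ever = ever_transferred_ids(cohort)
    rows = []
    for outcome, pp in pp_by_outcome.items():
        in_ever = pp["resident_id"].isin(ever)
        res = {}
        for label, sub in (("ever_transferred", pp[in_ever]), ("never_transferred", pp[~in_ever])):
            py = cohort_mod.person_years(sub)
            ev = int(sub["event"].sum())
            res[label] = (
                incidence_rate(ev, py, group=label)
                if py > 0
                else IncidenceResult(label, ev, 0.0, float("nan"), float("nan"), float("nan"))
            )
        e, n = res["ever_transferred"], res["never_transferred"]
        rr = rate_ratio(e, n) if n.person_years > 0 and n.rate_per_100py > 0 else None
        rows.append(
            {
                "outcome": outcome,
                "ever_events": e.events,
                "ever_person_years": e.person_years,
                "ever_rate_per_100py": e.rate_per_100py,
                "ever_ci_low": e.ci_low,
                "ever_ci_high": e.ci_high,
                "never_events": n.events,
                "never_person_years": n.person_years,
                "never_rate_per_100py": n.rate_per_100py,
                "never_ci_low": n.ci_low,
                "never_ci_high": n.ci_high,
                "irr": rr.ratio if rr else float("nan"),
                "irr_ci_low": rr.ci_low if rr else float("nan"),
                "irr_ci_high": rr.ci_high if rr else float("nan"),
            }
        )
    return pd.DataFrame(rows)


#: baseline variables summarised in the balance table
BASELINE_TABLE_VARIABLES = [
    ("age_at_admission", "continuous"),
    ("sex_female", "proportion"),
    ("adl_hierarchy", "continuous"),
    ("cps", "continuous"),
    ("chess", "continuous"),
    ("comorbidity_burden", "continuous"),
    ("fell_30d", "proportion"),
    ("weight_change_flag", "proportion"),
]


def baseline_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Balance of admission characteristics by ever/never transfer status."""
    ever = ever_transferred_ids(cohort)
    base = cohort[cohort["period_index"] == 0]
    a = base[base["resident_id"].isin(ever)]
    b = base[~base["resident_id"].isin(ever)]
    rows = []
    for var, kind in BASELINE_TABLE_VARIABLES:
        if kind == "continuous":
            sa = (float(a[var].mean()), float(a[var].std(ddof=1)))
            sb = (float(b[var].mean()), float(b[var].std(ddof=1)))
            smd = standardized_mean_difference(sa, sb, kind).smd if len(a) > 1 and len(b) > 1 else float("nan")
            rows.append(
                {
                    "variable": var,
                    "kind": kind,
                    "ever_mean": sa[0],
                    "ever_sd": sa[1],
                    "never_mean": sb[0],
                    "never_sd": sb[1],
                    "smd": smd,
                }
            )
        else:
            pa, pb = float(a[var].mean()), float(b[var].mean())
            smd = standardized_mean_difference(pa, pb, kind).smd
            rows.append(
                {
                    "variable": var,
                    "kind": kind,
                    "ever_mean": pa,
                    "ever_sd": float("nan"),
                    "never_mean": pb,
                    "never_sd": float("nan"),
                    "smd": smd,
                }
            )
    return pd.DataFrame(rows)
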