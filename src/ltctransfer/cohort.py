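"""Eligibility rules and person-period (counting-process) construction.

The analysis discretizes follow-up into 92-day windows indexed from
admission: window ``k`` covers days ``[92k, 92(k+1))``. Assessments are
indexed by the window they open, and a scale change first visible at
assessment ``t`` is attributed to window ``t``. A person-period row for
window ``k`` carries the exposure (any transfer in window ``k``) and
covariates of window ``k``, and its event is the outcome ascertained in the
immediately subsequent window ``k+1`` — for the first window, days 93–184
under 1-based day labels.

Follow-up ends at death, outcome onset (for that outcome's analysis),
administrative censoring after ``n_periods_max`` windows, or discharge from
care without readmission within 123 days (which makes the next assessment
unobservable; the discharge window is the last valid observation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SchemaError, validate_assessments
from .simulate import DAYS_PER_PERIOD

OUTCOME_EVENT_CODE = {
    "physical": "physical_impairment",
    "cognitive": "cognitive_impairment",
    "mortality": "death",
}

PERSON_PERIOD_COLUMNS = [
    "resident_id",
    "home_id",
    "period_index",
    "start_day",
    "stop_day",
    "exposed",
    "event",
    "event_code",
    "censor_reason",
    "age_at_admission",
    "sex_female",
    "comorbidity_burden",
    "baseline_adl",
    "baseline_cps",
    "baseline_chess",
    "adl_hierarchy",
    "cps",
    "chess",
    "weight_change_flag",
    "fell_30d",
    "prev_exposed",
    "cum_exposed_prior",
]

#: covariates measured once, at admission
BASELINE_COVARIATES = [
    "age_at_admission",
    "sex_female",
    "comorbidity_burden",
    "baseline_adl",
    "baseline_cps",
    "baseline_chess",
]

#: covariates updated at every assessment
TIME_VARYING_COVARIATES = ["chess", "weight_change_flag", "fell_30d"]


@dataclass
class EligibilityReport:
    """Accounting of cohort exclusions.

    At-risk counts are derived: residents remaining after the age filter,
    minus those already in the permanent state at admission.
    """

    n_input: int = 0
    n_excluded_age: int = 0
    n_excluded_prior_impairment_physical: int = 0
    n_excluded_prior_impairment_cognitive: int = 0

    @property
    def n_after_age(self) -> int:
        return self.n_input - self.n_excluded_age

    @property
    def n_at_risk_physical(self) -> int:
        return self.n_after_age - self.n_excluded_prior_impairment_physical

    @property
    def n_at_risk_cognitive(self) -> int:
        return self.n_after_age - self.n_excluded_prior_impairment_cognitive

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_excluded_age": self.n_excluded_age,
            "n_excluded_prior_impairment_physical": self.n_excluded_prior_impairment_physical,
            "n_excluded_prior_impairment_cognitive": self.n_excluded_prior_impairment_cognitive,
            "n_at_risk_physical": self.n_at_risk_physical,
            "n_at_risk_cognitive": self.n_at_risk_cognitive,
        }


def detect_permanent_impairment(
    scale_sequence, threshold_rule: str
) -> tuple[int | None, bool]:
    """Locate permanent impairment onset in a sequence of assessments.

    Onset is the first index from which the threshold holds at every later
    observed assessment ("no improvement in subsequent assessments"). A
    crossing reversed by a later improvement does not count, but a later
    re-crossing with no subsequent improvement does. A crossing that is the
    final observation counts as permanent.

    ``threshold_rule`` is ``"adl_eq_6"`` (total ADL dependence) or
    ``"cps_ge_5"`` (severe cognitive impairment / comatose).
    """
    seq = np.asarray(list(scale_sequence))
    if seq.size == 0:
        raise ValueError("scale sequence must be nonempty")
    if threshold_rule == "adl_eq_6":
        lo, hi = 0, 6
        meets = seq == 6
    elif threshold_rule == "cps_ge_5":
        lo, hi = 0, 6
        meets = seq >= 5
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    if ((seq < lo) | (seq > hi)).any():
        raise ValueError(f"scale values outside [{lo}, {hi}]: {seq!r}")
    suffix_all = np.flip(np.cumprod(np.flip(meets.astype(np.int8)))).astype(bool)
    if not suffix_all.any():
        return None, False
    return int(np.argmax(suffix_all)), True


def _onset_by_resident(real: pd.DataFrame, outcome: str) -> pd.Series:
    """Vectorized permanence rule over all residents; returns onset period."""
    if outcome == "physical":
        meets = real["adl_hierarchy"].eq(6)
    else:
        meets = real["cps"].ge(5)
    rev = pd.DataFrame(
        {"rid": real["resident_id"], "period": real["period_index"], "meets": meets}
    ).sort_values(["rid", "period"], ascending=[True, False], kind="mergesort")
    rev["suffix_all"] = rev.groupby("rid")["meets"].cumprod().astype(bool)
    hold = rev[rev["suffix_all"]]
    return hold.groupby("rid")["period"].min()


def apply_eligibility(
    table: pd.DataFrame, outcome: str
) -> tuple[pd.DataFrame, EligibilityReport]:
    """Apply age and baseline-impairment exclusions for one outcome.

    Residents under 65 at admission are always removed. For the physical
    (resp. cognitive) impairment outcome, residents already in the permanent
    state at admission (ADL hierarchy 6; CPS >= 5) are removed; the mortality
    analysis keeps them. The report tallies every exclusion for both scales
    regardless of the requested outcome.
    """
    if outcome not in OUTCOME_EVENT_CODE:
        raise ValueError(f"unknown outcome {outcome!r}")
    report = EligibilityReport(n_input=int(table["resident_id"].nunique()))
    if not len(table):
        return table.copy(), report
    validate_assessments(table)

    base = table[table["period_index"] == 0]
    too_young = base.loc[base["age_at_admission"] < 65, "resident_id"]
    report.n_excluded_age = int(too_young.nunique())
    aged = table[~table["resident_id"].isin(set(too_young))]
    base = aged[aged["period_index"] == 0]

    phys_prior = set(base.loc[base["adl_hierarchy"] == 6, "resident_id"])
    cog_prior = set(base.loc[base["cps"] >= 5, "resident_id"])
    report.n_excluded_prior_impairment_physical = len(phys_prior)
    report.n_excluded_prior_impairment_cognitive = len(cog_prior)

    if outcome == "physical":
        out = aged[~aged["resident_id"].isin(phys_prior)]
    elif outcome == "cognitive":
        out = aged[~aged["resident_id"].isin(cog_prior)]
    else:
        out = aged
    return out.reset_index(drop=True), report


def build_person_periods(
    table: pd.DataFrame, outcome: str, n_periods_max: int | None = None
) -> pd.DataFrame:
    """Convert an (eligible) assessment table to counting-process rows.

    One row per resident-window with ``[start_day, stop_day)`` of width 92,
    the binary exposure, baseline and time-varying covariates, and the
    terminal row's event code. Multiple transfers within one window collapse
    to ``exposed = 1``. The mortality analysis treats impairment as a
    covariate path, not an event.

    ``n_periods_max`` is the administrative horizon in 92-day windows
    (default: the largest period index present in the data).
    """
    if outcome not in OUTCOME_EVENT_CODE:
        raise ValueError(f"unknown outcome {outcome!r}")
    cols = pd.DataFrame(columns=PERSON_PERIOD_COLUMNS)
    if not len(table):
        return cols
    validate_assessments(table)
    df = table.sort_values(["resident_id", "period_index"], kind="mergesort").reset_index(
        drop=True
    )
    if n_periods_max is None:
        n_periods_max = int(df["period_index"].max())  # horizon implied by data
    terminal = (df["died_in_period"] == 1) | (df["discharged_in_period"] == 1)
    if (df.loc[terminal].groupby("resident_id").size() > 1).any():
        raise SchemaError("resident with more than one terminal status row")
    real = df[~terminal]

    rid_index = pd.Index(df["resident_id"].unique(), name="rid")
    inf = np.inf
    death_p = (
        df.loc[df["died_in_period"] == 1]
        .groupby("resident_id")["period_index"]
        .first()
        .reindex(rid_index, fill_value=inf)
        .astype(float)
    )
    disch_p = (
        df.loc[df["discharged_in_period"] == 1]
        .groupby("resident_id")["period_index"]
        .first()
        .reindex(rid_index, fill_value=inf)
        .astype(float)
    )
    if outcome in ("physical", "cognitive"):
        onset_p = _onset_by_resident(real, outcome).reindex(rid_index, fill_value=inf).astype(float)
    else:
        onset_p = pd.Series(inf, index=rid_index)

    cand = pd.DataFrame(
        {
            # precedence at equal terminal row: outcome event, then death,
            # then discharge censoring, then administrative censoring
            "event": onset_p - 1,
            "death": death_p - 1,
            "discharge": disch_p,
            "administrative": float(max(n_periods_max - 1, 0)),
        },
        index=rid_index,
    )
    last = cand.min(axis=1)
    ttype = cand.eq(last, axis=0).idxmax(axis=1)  # first True in column order
    keep = last >= 0
    last, ttype = last[keep].astype(int), ttype[keep]

    df = df.merge(
        pd.DataFrame({"resident_id": last.index, "_last": last.values, "_ttype": ttype.values}),
        on="resident_id",
        how="inner",
    )
    pp = df[df["period_index"] <= df["_last"]].copy()

    base = (
        pp[pp["period_index"] == 0]
        .set_index("resident_id")[["adl_hierarchy", "cps", "chess"]]
        .rename(
            columns={
                "adl_hierarchy": "baseline_adl",
                "cps": "baseline_cps",
                "chess": "baseline_chess",
            }
        )
    )
    pp = pp.join(base, on="resident_id")

    pp["start_day"] = pp["period_index"] * DAYS_PER_PERIOD
    pp["stop_day"] = (pp["period_index"] + 1) * DAYS_PER_PERIOD
    pp["exposed"] = (pp["transfer"] > 0).astype(int)
    g = pp.groupby("resident_id")["exposed"]
    pp["prev_exposed"] = g.shift(1, fill_value=0).astype(int)
    pp["cum_exposed_prior"] = (g.cumsum() - pp["exposed"]).astype(int)

    is_last = pp["period_index"] == pp["_last"]
    event_code = np.where(
        ~is_last,
        "none",
        np.select(
            [pp["_ttype"] == "event", pp["_ttype"] == "death"],
            [OUTCOME_EVENT_CODE[outcome], "death"],
            default="censored",
        ),
    )
    censor_reason = np.where(
        ~is_last,
        "",
        np.select(
            [
                pp["_ttype"] == "event",
                (pp["_ttype"] == "death") & (outcome == "mortality"),
                pp["_ttype"] == "death",
                pp["_ttype"] == "discharge",
            ],
            ["", "", "death", "discharge"],
            default="administrative",
        ),
    )
    pp["event_code"] = event_code
    pp["censor_reason"] = censor_reason
    pp["event"] = (pp["event_code"] == OUTCOME_EVENT_CODE[outcome]).astype(int)
    return pp[PERSON_PERIOD_COLUMNS].reset_index(drop=True)


def person_years(pp: pd.DataFrame) -> float:
    """Total person-time in years (365.25-day years) in a person-period table."""
    return float((pp["stop_day"] - pp["start_day"]).sum() / 365.25)
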