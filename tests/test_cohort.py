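import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ltctransfer as lt
from ltctransfer.cohort import detect_permanent_impairment, person_years


@pytest.mark.parametrize(
    "seq,rule,expected",
    [
        ([4, 5, 6, 6, 6], "adl_eq_6", (2, True)),
        ([4, 6, 5, 6, 6], "adl_eq_6", (3, True)),  # reversed crossing ignored
        ([3, 4, 4], "adl_eq_6", (None, False)),
        ([6], "adl_eq_6", (0, True)),  # final observation counts
        ([2, 5, 5], "cps_ge_5", (1, True)),
        ([2, 6, 4, 5], "cps_ge_5", (3, True)),
        ([5, 4, 5, 4], "cps_ge_5", (None, False)),
    ],
)
def test_permanence_rule_examples(seq, rule, expected):
    assert detect_permanent_impairment(seq, rule) == expected


def test_permanence_rule_rejects_bad_input():
    with pytest.raises(ValueError):
        detect_permanent_impairment([], "adl_eq_6")
    with pytest.raises(ValueError):
        detect_permanent_impairment([7], "adl_eq_6")
    with pytest.raises(ValueError):
        detect_permanent_impairment([3], "nope")


@given(st.lists(st.integers(0, 6), min_size=1, max_size=12))
def test_permanence_rule_matches_naive_scan(seq):
    onset, found = detect_permanent_impairment(seq, "adl_eq_6")
    naive = next(
        (i for i in range(len(seq)) if all(v == 6 for v in seq[i:])),
        None,
    )
    assert (onset, found) == (naive, naive is not None)


def test_eligibility_excludes_age_and_baseline_impairment():
    base = dict(
        home_id="h0",
        age_at_admission=80.0,
        sex_female=1,
        chess=0,
        comorbidity_burden=2,
        weight_change_flag=0,
        fell_30d=0,
        transfer=0,
        died_in_period=0,
        discharged_in_period=0,
    )
    rows = [
        {**base, "resident_id": "a", "period_index": 0, "adl_hierarchy": 3, "cps": 1},
        {**base, "resident_id": "a", "period_index": 1, "adl_hierarchy": 3, "cps": 1},
        {**base, "resident_id": "b", "period_index": 0, "adl_hierarchy": 6, "cps": 1},
        {**base, "resident_id": "c", "period_index": 0, "adl_hierarchy": 2, "cps": 5},
        {**base, "resident_id": "d", "period_index": 0, "adl_hierarchy": 1, "cps": 0,
         "age_at_admission": 40.0},
    ]
    table = pd.DataFrame(rows)
    elig_p, rep_p = lt.apply_eligibility(table, "physical")
    assert set(elig_p["resident_id"]) == {"a", "c"}
    assert rep_p.n_input == 4 and rep_p.n_excluded_age == 1
    assert rep_p.n_excluded_prior_impairment_physical == 1
    assert rep_p.n_at_risk_physical == 2
    elig_c, rep_c = lt.apply_eligibility(table, "cognitive")
    assert set(elig_c["resident_id"]) == {"a", "b"}
    assert rep_c.n_at_risk_cognitive == 2


def _oracle_person_periods(cohort, outcome, n_periods_max):
    """Per-resident day-scanner oracle for the counting-process rules."""
    out = {}
    for rid, g in cohort.sort_values("period_index").groupby("resident_id"):
        periods = g["period_index"].to_numpy()
        cands = {}
        if outcome in ("physical", "cognitive"):
            col = "adl_hierarchy" if outcome == "physical" else "cps"
            rule = "adl_eq_6" if outcome == "physical" else "cps_ge_5"
            onset, found = detect_permanent_impairment(g[col].to_numpy(), rule)
            if found:
                cands["event"] = periods[onset] - 1
        if g["died_in_period"].any():
            d = periods[g["died_in_period"].to_numpy().astype(bool)][0]
            key = "event" if outcome == "mortality" else "death"
            if key not in cands:
                cands[key] = d - 1
        if g["discharged_in_period"].any():
            cands["discharge"] = periods[g["discharged_in_period"].to_numpy().astype(bool)][0]
        cands["administrative"] = n_periods_max - 1
        last = min(cands.values())
        for reason in ("event", "death", "discharge", "administrative"):
            if cands.get(reason) == last:
                break
        if last < 0:
            continue
        out[rid] = (last, reason)
    return out


@pytest.mark.parametrize("outcome", ["physical", "cognitive", "mortality"])
def test_person_periods_match_day_scanner_oracle(small_cohort, small_config, outcome):
    eligible, _ = lt.apply_eligibility(small_cohort, outcome)
    pp = lt.build_person_periods(eligible, outcome, n_periods_max=small_config.n_periods_max)
    oracle = _oracle_person_periods(eligible, outcome, small_config.n_periods_max)
    got = pp.groupby("resident_id").tail(1).set_index("resident_id")
    assert set(got.index) == set(oracle)
    for rid, (last, reason) in oracle.items():
        row = got.loc[rid]
        assert row["period_index"] == last, rid
        if reason == "event":
            assert row["event"] == 1
        else:
            assert row["event"] == 0
            expect = "death" if reason == "death" else reason
            assert row["censor_reason"] == expect, (rid, reason, row["censor_reason"])


def test_person_period_structure(pp_mortality):
    assert ((pp_mortality["stop_day"] - pp_mortality["start_day"]) == 92).all()
    assert (pp_mortality["start_day"] == 92 * pp_mortality["period_index"]).all()
    # events only on final rows, one row per resident-period
    dup = pp_mortality.duplicated(["resident_id", "period_index"])
    assert not dup.any()
    nonlast = pp_mortality.sort_values("period_index").groupby("resident_id").apply(
        lambda g: g.iloc[:-1]["event"].sum(), include_groups=False
    )
    assert (nonlast == 0).all()


def test_exposure_alignment(small_cohort, pp_mortality):
    merged = pp_mortality.merge(
        small_cohort[["resident_id", "period_index", "transfer"]],
        on=["resident_id", "period_index"],
        how="left",
    )
    assert (merged["exposed"] == merged["transfer"]).all()


def test_person_years():
    pp = pd.DataFrame({"start_day": [0, 92], "stop_day": [92, 184]})
    assert person_years(pp) == pytest.approx(184 / 365.25)


def test_unknown_outcome_raises(small_cohort):
    with pytest.raises(ValueError):
        lt.apply_eligibility(small_cohort, "fractures")
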