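import numpy as np
import pandas as pd
import pytest

import ltctransfer as lt
from ltctransfer.msm import (
    WeightModelSpec,
    compute_stabilized_weights,
    estimate_weights,
    fit_crude_cox,
    fit_msm,
    fit_treatment_models,
)


def test_weight_arithmetic_by_hand():
    probs = pd.DataFrame(
        {
            "resident_id": ["a", "a", "b"],
            "period_index": [0, 1, 0],
            "p_num_treat": [0.5, 0.4, 0.6],
            "p_den_treat": [0.25, 0.8, 0.6],
            "p_num_cens": [1.0, 0.9, 1.0],
            "p_den_cens": [1.0, 0.95, 1.0],
        }
    )
    ws = compute_stabilized_weights(probs, truncation=None)
    sw = ws.table.set_index(["resident_id", "period_index"])
    assert sw.loc[("a", 0), "sw_period"] == pytest.approx(2.0)
    assert sw.loc[("a", 1), "sw_period"] == pytest.approx((0.4 / 0.8) * (0.9 / 0.95))
    # running product within resident
    assert sw.loc[("a", 1), "sw_cum"] == pytest.approx(2.0 * 0.5 * (0.9 / 0.95))
    assert sw.loc[("b", 0), "sw_cum"] == pytest.approx(1.0)
    assert (ws.table["truncated"] == 0).all()


def test_truncation_clips_at_percentiles():
    n = 200
    probs = pd.DataFrame(
        {
            "resident_id": [f"r{i}" for i in range(n)],
            "period_index": 0,
            "p_num_treat": 0.5,
            "p_den_treat": np.linspace(0.05, 0.95, n),
            "p_num_cens": 1.0,
            "p_den_cens": 1.0,
        }
    )
    ws = compute_stabilized_weights(probs, truncation=(5.0, 95.0))
    raw = 0.5 / np.linspace(0.05, 0.95, n)
    lo, hi = np.percentile(raw, [5, 95])
    assert ws.table["sw_cum"].max() == pytest.approx(hi)
    assert ws.table["sw_cum"].min() == pytest.approx(lo)
    assert ws.table["truncated"].sum() > 0


def test_bad_probabilities_rejected():
    probs = pd.DataFrame(
        {
            "resident_id": ["a"],
            "period_index": [0],
            "p_num_treat": [0.5],
            "p_den_treat": [0.0],
            "p_num_cens": [1.0],
            "p_den_cens": [1.0],
        }
    )
    with pytest.raises(ValueError):
        compute_stabilized_weights(probs)


def test_spec_validates_nesting():
    with pytest.raises(ValueError):
        WeightModelSpec(
            denominator_covariates=["chess"],
            numerator_covariates=["not_a_column_of_denominator"],
        )


def test_mean_stabilized_weight_near_one(pp_mortality):
    ws = estimate_weights(pp_mortality, WeightModelSpec(truncation=None))
    diag = ws.diagnostics()
    assert ((diag["mean"] > 0.85) & (diag["mean"] < 1.15)).all()
    merged = pp_mortality.merge(
        ws.table[["resident_id", "period_index", "sw_cum"]],
        on=["resident_id", "period_index"],
    )
    assert len(merged) == len(pp_mortality)
    assert abs(merged["sw_cum"].mean() - 1.0) < 0.1


def test_no_censoring_gives_unit_censor_probs(pp_mortality):
    pp = pp_mortality.copy()
    pp.loc[pp["censor_reason"] == "discharge", "censor_reason"] = "administrative"
    probs = fit_treatment_models(pp, WeightModelSpec())
    assert (probs["p_num_cens"] == 1.0).all()
    assert (probs["p_den_cens"] == 1.0).all()


def test_unit_weights_reproduce_unweighted_fit(pp_mortality):
    spec = WeightModelSpec()
    probs = fit_treatment_models(pp_mortality, spec)
    unit = probs.assign(
        p_num_treat=0.5, p_den_treat=0.5, p_num_cens=1.0, p_den_cens=1.0
    )
    ws = compute_stabilized_weights(unit, truncation=None)
    est_w = fit_msm(pp_mortality, ws, "mortality", spec)
    from ltctransfer.cox import CoxSpec, fit_cox

    covs = ["exposed"] + list(spec.numerator_covariates)
    ref = fit_cox(pp_mortality, CoxSpec(covariates=covs, cluster_col="home_id"))
    assert est_w.log_hr == pytest.approx(ref.coef("exposed"), abs=1e-10)
    assert est_w.extra["mean_weight"] == pytest.approx(1.0)


def test_msm_removes_measured_confounding():
    cfg = lt.SimulationConfig.measured_confounding(
        n_homes=20, residents_per_home=150, seed=42
    )
    sim = lt.simulate(cfg)
    eligible, _ = lt.apply_eligibility(sim.assessments, "mortality")
    pp = lt.build_person_periods(eligible, "mortality", n_periods_max=cfg.n_periods_max)
    spec = WeightModelSpec(truncation=None)
    ws = estimate_weights(pp, spec)
    msm = fit_msm(pp, ws, "mortality", spec)
    crude = fit_crude_cox(pp, "mortality")
    truth = cfg.beta_transfer["death"]
    # the weighted estimate must sit closer to the planted value than crude
    assert abs(msm.log_hr - truth) < abs(crude.log_hr - truth)
    assert crude.log_hr > truth  # confounding is planted upward


def test_estimates_expose_robust_ci(pp_mortality):
    est = fit_crude_cox(pp_mortality, "mortality")
    assert est.ci_low < est.hr < est.ci_high
    assert est.n_events == int(pp_mortality["event"].sum())
    d = est.to_dict()
    assert {"estimator", "outcome", "hr", "hr_ci_low", "hr_ci_high"} <= set(d)
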