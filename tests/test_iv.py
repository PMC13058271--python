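import numpy as np
import pandas as pd
import pytest

import ltctransfer as lt
from ltctransfer.cox import CoxSpec, fit_cox
from ltctransfer.iv import (
    WeakInstrumentWarning,
    attach_instrument,
    compute_instrument,
    control_function_cox,
    first_stage,
    fit_iv,
    instrument_diagnostics,
)


def _tiny_cohort_and_history():
    rows = []
    # home h0: 3 residents, resident r0 transferred in periods 1 and 5,
    # r1 transferred in period 2; home h1: 2 residents, none transferred
    for rid, home, transfers in (
        ("r0", "h0", {1, 5}),
        ("r1", "h0", {2}),
        ("r2", "h0", set()),
        ("r3", "h1", set()),
        ("r4", "h1", set()),
    ):
        for t in range(9):
            rows.append(
                {
                    "home_id": home,
                    "resident_id": rid,
                    "period_index": t,
                    "transfer": int(t in transfers),
                }
            )
    cohort = pd.DataFrame(rows)
    history = pd.DataFrame(
        {
            "home_id": ["h0", "h1"],
            "n_residents_prior_year": [10, 0],
            "n_transferred_prior_year": [4, 0],
        }
    )
    return cohort, history


def test_compute_instrument_arithmetic():
    cohort, history = _tiny_cohort_and_history()
    inst = compute_instrument(cohort, history).set_index(["home_id", "year"])
    # year 0 comes from the burn-in history block
    assert inst.loc[("h0", 0), "z"] == pytest.approx(0.4)
    assert np.isnan(inst.loc[("h1", 0), "z"])  # no prior-year residents
    # year 1 uses periods 0-3: r0 and r1 each transferred at least once
    assert inst.loc[("h0", 1), "z"] == pytest.approx(2 / 3)
    assert inst.loc[("h1", 1), "z"] == 0.0
    # year 2 uses periods 4-7: only r0 transferred (period 5)
    assert inst.loc[("h0", 2), "z"] == pytest.approx(1 / 3)
    assert inst.loc[("h0", 2), "n_residents_prior_year"] == 3


def test_attach_instrument_maps_and_drops_missing():
    cohort, history = _tiny_cohort_and_history()
    inst = compute_instrument(cohort, history)
    pp = pd.DataFrame(
        {
            "home_id": ["h0", "h0", "h1"],
            "resident_id": ["r0", "r0", "r3"],
            "period_index": [0, 4, 1],
        }
    )
    with pytest.warns(UserWarning, match="missing instrument"):
        out = attach_instrument(pp, inst)
    # h1 year 0 has no z -> the h1 row is dropped
    assert len(out) == 2
    assert out["z"].tolist() == pytest.approx([0.4, 2 / 3])
    fixed = attach_instrument(pp[pp["home_id"] == "h0"], inst, fixed_at_admission=True)
    assert (fixed["z"] == 0.4).all()


def test_instrument_correlates_with_planted_theta(small_sim):
    inst = compute_instrument(small_sim.assessments, small_sim.home_history)
    z0 = inst[inst["year"] == 0].set_index("home_id")["z"]
    theta = small_sim.truth.home_theta.set_index("home_id")["theta"]
    r = np.corrcoef(z0.loc[theta.index], theta)[0, 1]
    assert r > 0.5


def test_first_stage_relevance_on_simulated_data(small_sim, small_config, pp_mortality):
    inst = compute_instrument(small_sim.assessments, small_sim.home_history)
    pp_z = attach_instrument(pp_mortality, inst)
    s1 = first_stage(pp_z)
    assert s1.wald_z > 2.0
    assert not s1.weak
    assert s1.params["z"] > 0
    # residuals are observed minus fitted and sum to ~0 with an intercept
    assert s1.residuals.abs().max() <= 1.0
    assert abs(s1.residuals.mean()) < 0.01


def test_degenerate_instrument_warns_weak():
    n = 400
    rng = np.random.default_rng(0)
    pp = pd.DataFrame(
        {
            "exposed": rng.binomial(1, 0.3, n),
            "z": np.full(n, 0.25),
            "age_at_admission": rng.normal(84, 7, n),
        }
    )
    with pytest.warns(WeakInstrumentWarning):
        s1 = first_stage(pp, covariates=["age_at_admission"])
    assert s1.weak and s1.wald_z == 0.0 and s1.params["z"] == 0.0


def test_control_function_without_residual_is_adjusted_cox(
    small_sim, pp_mortality
):
    inst = compute_instrument(small_sim.assessments, small_sim.home_history)
    pp_z = attach_instrument(pp_mortality, inst)
    s1 = first_stage(pp_z)
    ivf = control_function_cox(pp_z, s1, "mortality", include_residual=False)
    from ltctransfer.cohort import BASELINE_COVARIATES

    ref = fit_cox(
        pp_z,
        CoxSpec(covariates=["exposed"] + BASELINE_COVARIATES, cluster_col="home_id"),
    )
    assert ivf.estimate.log_hr == pytest.approx(ref.coef("exposed"), abs=1e-10)
    assert ivf.residual_coef == 0.0 and np.isnan(ivf.residual_se)


def test_fit_iv_end_to_end(small_sim, pp_mortality):
    ivf = fit_iv(pp_mortality, small_sim.assessments, small_sim.home_history, "mortality")
    est = ivf.estimate
    assert est.estimator == "iv" and est.outcome == "mortality"
    assert est.ci_low < est.hr < est.ci_high
    assert est.converged
    assert "extra_stage1_wald_z" in est.to_dict()


def test_bootstrap_ci_runs_and_is_deterministic(small_sim, pp_mortality):
    kwargs = dict(ci_method="bootstrap", n_boot=25, seed=11)
    a = fit_iv(pp_mortality, small_sim.assessments, small_sim.home_history, "mortality", **kwargs)
    b = fit_iv(pp_mortality, small_sim.assessments, small_sim.home_history, "mortality", **kwargs)
    assert a.estimate.ci_low == b.estimate.ci_low
    assert a.estimate.ci_high == b.estimate.ci_high
    assert a.n_boot == 25 and len(a.boot_estimates) + a.boot_failures == 25
    assert a.estimate.ci_low < a.estimate.ci_high


def test_unknown_ci_method_raises(small_sim, pp_mortality):
    with pytest.raises(ValueError):
        fit_iv(
            pp_mortality,
            small_sim.assessments,
            small_sim.home_history,
            "mortality",
            ci_method="jackknife",
        )


def test_instrument_diagnostics_outputs(small_sim):
    inst = compute_instrument(small_sim.assessments, small_sim.home_history)
    diag = instrument_diagnostics(small_sim.assessments, inst)
    assert diag["relevance_wald_z"] > 0
    assert set(diag["baseline_smd"]["variable"]) >= {"age_at_admission", "sex_female"}
    qi = diag["quintile_incidence"]
    assert diag["n_quintiles"] == 5
    n0 = small_sim.assessments["resident_id"].nunique()
    assert qi["n_residents"].sum() == n0
    # higher-preference homes transfer more residents
    assert (
        qi.set_index("quintile").loc[5, "prop_ever_transferred"]
        > qi.set_index("quintile").loc[1, "prop_ever_transferred"]
    )


def test_diagnostics_require_two_homes(small_sim):
    one = small_sim.assessments[small_sim.assessments["home_id"] == small_sim.assessments["home_id"].iloc[0]]
    inst = compute_instrument(small_sim.assessments, small_sim.home_history)
    with pytest.raises(ValueError):
        instrument_diagnostics(one, inst[inst["home_id"] == one["home_id"].iloc[0]])
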