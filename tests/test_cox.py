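import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import ltctransfer as lt
from ltctransfer.cox import CoxSpec, fit_cox

from conftest import toy_cox_data


def brute_force_neg_pl(df, beta, ties="efron"):
    """Literal partial-likelihood evaluation by explicit risk-set loops."""
    eta = beta * df["x"].to_numpy()
    w = df["w"].to_numpy() if "w" in df else np.ones(len(df))
    start = df["start_day"].to_numpy()
    stop = df["stop_day"].to_numpy()
    event = df["event"].to_numpy().astype(bool)
    ll = 0.0
    for t in np.unique(stop[event]):
        at_risk = (start < t) & (stop >= t)
        deaths = at_risk & event & (stop == t)
        idx_d = np.where(deaths)[0]
        m = len(idx_d)
        wbar = w[idx_d].mean()
        s0_risk = np.sum(w[at_risk] * np.exp(eta[at_risk]))
        s0_dead = np.sum(w[idx_d] * np.exp(eta[idx_d]))
        ll += np.sum(w[idx_d] * eta[idx_d])
        for l in range(m):
            frac = l / m if ties == "efron" else 0.0
            ll -= wbar * np.log(s0_risk - frac * s0_dead)
    return -ll


@pytest.mark.parametrize(
    "rows",
    [
        # (start, stop, event, x, w)
        [(0, 92, 1, 0.5, 1.0), (0, 92, 0, 1.0, 1.0), (0, 184, 1, 0.0, 1.0)],
        [(0, 92, 1, 1.0, 2.0), (0, 92, 1, 0.0, 1.0), (0, 184, 0, 1.0, 1.5),
         (92, 184, 1, -1.0, 1.0)],
        [(0, 92, 1, 0.2, 1.0), (0, 184, 1, -0.4, 1.0), (0, 276, 1, 1.1, 1.0),
         (0, 276, 0, 0.0, 1.0), (92, 276, 1, 0.6, 1.0), (0, 92, 0, -0.3, 1.0)],
    ],
)
@pytest.mark.parametrize("ties", ["efron", "breslow"])
def test_engine_matches_brute_force_on_tiny_data(rows, ties):
    df = pd.DataFrame(rows, columns=["start_day", "stop_day", "event", "x", "w"])
    fit = fit_cox(df, CoxSpec(covariates=["x"], ties=ties, weight_col="w"))
    res = minimize_scalar(
        lambda b: brute_force_neg_pl(df, b, ties), bounds=(-10, 10), method="bounded",
        options={"xatol": 1e-10},
    )
    assert fit.coefficients[0] == pytest.approx(res.x, abs=1e-6)
    assert -fit.loglik == pytest.approx(res.fun, abs=1e-8)


def test_breslow_equals_efron_without_ties():
    rng = np.random.default_rng(5)
    n = 40
    df = pd.DataFrame(
        {
            "start_day": np.zeros(n),
            "stop_day": rng.permutation(np.arange(1, n + 1)).astype(float),
            "event": rng.binomial(1, 0.6, n),
            "x": rng.normal(size=n),
        }
    )
    fe = fit_cox(df, CoxSpec(covariates=["x"], ties="efron"))
    fb = fit_cox(df, CoxSpec(covariates=["x"], ties="breslow"))
    assert fe.coefficients[0] == pytest.approx(fb.coefficients[0], abs=1e-10)
    assert fe.loglik == pytest.approx(fb.loglik, abs=1e-10)


def test_matches_lifelines_on_tied_weighted_data():
    lifelines = pytest.importorskip("lifelines")
    df = toy_cox_data(seed=9, n=250)
    fit = fit_cox(df, CoxSpec(covariates=["x1", "x2"]))
    ctv = lifelines.CoxTimeVaryingFitter()
    ctv.fit(
        df.rename(columns={"id": "pid"}),
        id_col="pid",
        start_col="start_day",
        stop_col="stop_day",
        event_col="event",
        formula="x1 + x2",
    )
    ref = ctv.params_[["x1", "x2"]].to_numpy()
    ref_se = ctv.standard_errors_[["x1", "x2"]].to_numpy()
    assert np.allclose(fit.coefficients, ref, atol=1e-6)
    assert np.allclose(fit.model_se, ref_se, atol=1e-6)
    assert fit.loglik == pytest.approx(ctv.log_likelihood_, abs=1e-6)


def test_score_residual_columns_sum_to_zero_at_optimum():
    from ltctransfer.cox import _PartialLikelihood

    df = toy_cox_data(seed=2, n=200)
    fit = fit_cox(df, CoxSpec(covariates=["x1", "x2"]))
    pl = _PartialLikelihood(
        df[["x1", "x2"]].to_numpy(float),
        np.ones(len(df)),
        df["start_day"].to_numpy(float),
        df["stop_day"].to_numpy(float),
        df["event"].to_numpy(bool),
        "efron",
    )
    resid = pl.score_residuals(fit.coefficients)
    assert np.allclose(resid.sum(axis=0), 0.0, atol=1e-8)


def test_cluster_duplication_scales_robust_se():
    # Breslow ties: the partial likelihood is exactly invariant (up to a
    # constant) under duplicating every row, unlike Efron where the
    # within-tie fractions change
    df = toy_cox_data(seed=4, n=150)
    spec = CoxSpec(covariates=["x1", "x2"], cluster_col="cluster", ties="breslow")
    fit1 = fit_cox(df, spec)
    # duplicating rows inside their original clusters leaves the clustered
    # sandwich invariant: A and the cluster score sums both double
    dup_same = pd.concat([df, df], ignore_index=True)
    fit2 = fit_cox(dup_same, spec)
    assert np.allclose(fit1.coefficients, fit2.coefficients, atol=1e-8)
    assert np.allclose(fit2.robust_se, fit1.robust_se, rtol=1e-6)
    # duplicating as fresh clusters is two independent copies: SE / sqrt(2)
    dup_new = pd.concat([df, df.assign(cluster=df["cluster"] + 100)], ignore_index=True)
    fit3 = fit_cox(dup_new, spec)
    assert np.allclose(fit3.robust_se * np.sqrt(2), fit1.robust_se, rtol=1e-6)


def test_weight_invariance_constant_rescale():
    df = toy_cox_data(seed=6, n=150)
    df["w"] = 1.0
    f1 = fit_cox(df, CoxSpec(covariates=["x1", "x2"], weight_col="w"))
    df["w"] = 2.5
    f2 = fit_cox(df, CoxSpec(covariates=["x1", "x2"], weight_col="w"))
    assert np.allclose(f1.coefficients, f2.coefficients, atol=1e-8)


def test_estimation_errors():
    df = pd.DataFrame(
        {"start_day": [0, 0], "stop_day": [92, 92], "event": [0, 0], "x": [1.0, 0.0]}
    )
    with pytest.raises(lt.EstimationError):
        fit_cox(df, CoxSpec(covariates=["x"]))  # no events
    df2 = df.assign(event=[1, 0], w=[-1.0, 1.0])
    with pytest.raises(lt.EstimationError):
        fit_cox(df2, CoxSpec(covariates=["x"], weight_col="w"))
    with pytest.raises(lt.EstimationError):
        fit_cox(df.assign(event=[1, 0]), CoxSpec(covariates=["missing"]))


def test_separation_warns():
    # monotone likelihood with a small covariate gap: the coefficient must
    # run past the divergence bound before the score can vanish
    df = pd.DataFrame(
        {
            "start_day": [0.0] * 6,
            "stop_day": [92.0] * 5 + [184.0],
            "event": [1, 0, 0, 0, 0, 0],
            "x": [1.0, 0.9, 0.8, 0.7, 0.6, 0.5],
        }
    )
    with pytest.warns(UserWarning, match="separation|diverging"):
        fit = fit_cox(df, CoxSpec(covariates=["x"]))
    assert fit.separation
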