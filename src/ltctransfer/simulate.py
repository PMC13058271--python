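"""Discrete-time simulator for longitudinal long-term-care cohorts.

Generates RAI-MDS-2.0-style quarterly assessment tables on a 92-day grid,
with the statistical structure the downstream causal analyses assume:

* between-home variation in the per-period propensity to transfer residents
  to hospital (``theta``, the preference-based instrument);
* a latent, transient acute-illness process (with a resident-level frailty)
  that raises both the transfer probability and all outcome hazards — the
  unmeasured confounding pathway;
* measured time-varying confounders (CHESS health instability, falls,
  weight change) that respond to past transfer and illness;
* known true causal log hazard ratios of transfer on permanent physical
  impairment, permanent cognitive impairment and death.

Event timing matches the analysis' clock: an event in window ``k+1`` is
generated from exposure, illness and covariates of window ``k``, so the
person-period row for window ``k`` carries exactly the information that
caused (or did not cause) its ascertained outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import ConfigurationError, SimulationConfig

DAYS_PER_PERIOD = 92

#: analysis-facing assessment columns, in file order (latent fields excluded)
ASSESSMENT_COLUMNS = [
    "resident_id",
    "home_id",
    "period_index",
    "age_at_admission",
    "sex_female",
    "adl_hierarchy",
    "cps",
    "chess",
    "comorbidity_burden",
    "weight_change_flag",
    "fell_30d",
    "transfer",
    "died_in_period",
    "discharged_in_period",
]

TRUTH_COLUMNS = ["resident_id", "period_index", "acute_illness", "frailty"]

HOME_COLUMNS = ["home_id", "n_residents_prior_year", "n_transferred_prior_year"]


@dataclass(frozen=True)
class HomeProfile:
    """A long-term-care home with a latent per-period transfer propensity."""

    home_id: str
    theta: float
    n_residents: int


@dataclass
class TruthTable:
    """Latent ground truth for parameter-recovery tests.

    Never read by the analysis modules: it records the per-period acute
    illness indicator and resident frailty, the true causal log hazard
    ratios used, the home propensities, and an echo of the configuration.
    """

    table: pd.DataFrame
    home_theta: pd.DataFrame  # home_id, theta
    true_log_hr: dict[str, float]
    config_json: str


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_cohort`."""

    assessments: pd.DataFrame
    home_history: pd.DataFrame
    truth: TruthTable


def simulate_homes(config: SimulationConfig) -> list[HomeProfile]:
    """Create home profiles whose transfer propensities span ``theta_range``.

    Propensities are placed on an evenly spaced grid over the configured
    range (midpoint for a single home), which guarantees the between-home
    spread the preference-based instrument needs regardless of sample size.
    """
    lo, hi = config.theta_range
    n = config.n_homes
    if n == 1:
        thetas = np.array([(lo + hi) / 2.0])
    else:
        thetas = np.linspace(lo, hi, n)
    return [
        HomeProfile(home_id=f"h{i:03d}", theta=float(t), n_residents=config.residents_per_home)
        for i, t in enumerate(thetas)
    ]


def _covariate_lp(effects: dict[str, float], cov: dict[str, np.ndarray]) -> np.ndarray:
    """Linear predictor contribution of measured covariates.

    Covariates are centered at their reference levels so the configured
    baseline hazards apply at CHESS 1, age 85, no falls/weight change,
    ADL 3, 3 comorbidities, male.
    """
    n = len(cov["chess"])
    lp = np.zeros(n)
    for name, beta in effects.items():
        if name not in cov:
            raise ConfigurationError(
                f"unknown covariate {name!r} in covariate_effects; "
                f"known: {sorted(cov)}"
            )
        lp += beta * cov[name]
    return lp


def _centered_covariates(
    age: np.ndarray,
    sex: np.ndarray,
    adl: np.ndarray,
    chess: np.ndarray,
    comorb: np.ndarray,
    fell: np.ndarray,
    wchange: np.ndarray,
) -> dict[str, np.ndarray]:
    return {
        "age_c": age - 85.0,
        "sex_female": sex.astype(float),
        "adl_c": adl - 3.0,
        "chess": chess - 1.0,
        "comorbidity_c": comorb - 3.0,
        "fell_30d": fell.astype(float),
        "weight_change_flag": wchange.astype(float),
    }


def _grouped_ph_prob(h0: float, lp: np.ndarray) -> np.ndarray:
    """Per-period event probability under grouped proportional hazards.

    ``p = 1 - (1 - h0)^exp(lp)`` keeps probabilities in [0, 1) while making
    the planted coefficients exact cause-specific log hazard ratios.
    """
    if h0 <= 0.0:
        return np.zeros_like(lp)
    return 1.0 - np.power(1.0 - h0, np.exp(lp))


def _marginal_transfer_prob(cfg: SimulationConfig, theta: np.ndarray) -> np.ndarray:
    """Per-period transfer probability at reference covariates for each home.

    Mixes the healthy- and ill-state transfer probabilities, with the
    illness probability averaged over the Gaussian frailty distribution by
    Gauss-Hermite quadrature.
    """
    logit_theta = logit(theta)
    nodes, weights = np.polynomial.hermite_e.hermegauss(21)
    f = cfg.frailty_sd * nodes  # frailty quadrature points
    w = weights / weights.sum()
    if cfg.p_illness > 0:
        p_ill_marg = float(np.sum(w * expit(logit(cfg.p_illness) + f)))
    else:
        p_ill_marg = 0.0
    p_healthy = expit(logit_theta)
    p_sick = expit(logit_theta + cfg.gamma_illness_transfer)
    return (1.0 - p_ill_marg) * p_healthy + p_ill_marg * p_sick


def simulate_cohort(
    config: SimulationConfig, homes: list[HomeProfile]
) -> SimulatedCohort:
    """Simulate the longitudinal assessment table plus ground truth.

    Residents are followed from admission (period 0) until death, discharge,
    or the administrative horizon at ``n_periods_max`` periods. Events in
    window ``t`` are generated from exposure/illness/covariates of window
    ``t - 1``; terminal rows carry ``died_in_period`` or
    ``discharged_in_period`` flags in the window the event occurred.
    """
    if not homes:
        raise ConfigurationError("homes must be nonempty")
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    s_hist, s_base, s_path = ss.spawn(3)
    rng_hist = np.random.default_rng(s_hist)
    rng_base = np.random.default_rng(s_base)
    rng = np.random.default_rng(s_path)

    # -- home burn-in history (prior-year transfer counts for the IV) -----
    # The prior-year counts are drawn from the same transfer process the
    # follow-up uses (home propensity plus illness gating, at reference
    # covariates), marginalized over the frailty distribution, so the
    # year-0 instrument measures the same quantity as later years.
    theta_by_home = np.array([h.theta for h in homes])
    n_res_by_home = np.array([h.n_residents for h in homes])
    p_period = _marginal_transfer_prob(cfg, theta_by_home)
    p_ever_year = 1.0 - (1.0 - p_period) ** 4
    n_transferred_hist = rng_hist.binomial(n_res_by_home, p_ever_year)
    home_history = pd.DataFrame(
        {
            "home_id": [h.home_id for h in homes],
            "n_residents_prior_year": n_res_by_home,
            "n_transferred_prior_year": n_transferred_hist,
        }
    )

    # -- baseline resident draws ------------------------------------------
    n = int(n_res_by_home.sum())
    home_idx = np.repeat(np.arange(len(homes)), n_res_by_home)
    theta = theta_by_home[home_idx]
    home_ids = np.array([h.home_id for h in homes])[home_idx]
    resident_ids = np.array([f"r{i:06d}" for i in range(n)])

    age = np.clip(rng_base.normal(84.6, 7.9, n), 65.0, 105.0)
    sex = rng_base.random(n) < 0.66
    adl = rng_base.choice(7, n, p=[0.03, 0.065, 0.17, 0.30, 0.235, 0.17, 0.03])
    cps = rng_base.choice(7, n, p=[0.15, 0.115, 0.235, 0.34, 0.073, 0.062, 0.025])
    chess = rng_base.choice(6, n, p=[0.465, 0.345, 0.135, 0.04, 0.011, 0.004])
    comorb = np.clip(rng_base.poisson(3.0, n), 0, 10)
    frailty = rng_base.normal(0.0, cfg.frailty_sd, n)

    perm_phys = adl == 6
    perm_cog = cps >= 5

    rows: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []

    def emit(
        mask: np.ndarray,
        t: int,
        transfer: np.ndarray,
        illness: np.ndarray,
        died: np.ndarray,
        discharged: np.ndarray,
    ) -> None:
        idx = np.flatnonzero(mask)
        rows.append(
            pd.DataFrame(
                {
                    "resident_id": resident_ids[idx],
                    "home_id": home_ids[idx],
                    "period_index": t,
                    "age_at_admission": age[idx],
                    "sex_female": sex[idx].astype(int),
                    "adl_hierarchy": adl[idx],
                    "cps": cps[idx],
                    "chess": chess[idx],
                    "comorbidity_burden": comorb[idx],
                    "weight_change_flag": wchange[idx].astype(int),
                    "fell_30d": fell[idx].astype(int),
                    "transfer": transfer[idx].astype(int),
                    "died_in_period": died[idx].astype(int),
                    "discharged_in_period": discharged[idx].astype(int),
                }
            )
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "resident_id": resident_ids[idx],
                    "period_index": t,
                    "acute_illness": illness[idx].astype(int),
                    "frailty": frailty[idx],
                }
            )
        )

    # -- period 0 ----------------------------------------------------------
    active = np.ones(n, dtype=bool)
    illness = rng.random(n) < expit(logit(cfg.p_illness) + frailty)
    fell = rng.random(n) < expit(-1.8 + 0.3 * (adl >= 4))
    wchange = rng.random(n) < np.clip(0.08 + 0.15 * illness, 0.0, 1.0)
    cov = _centered_covariates(age, sex, adl, chess, comorb, fell, wchange)
    p_tr = expit(
        logit(theta)
        + cfg.gamma_illness_transfer * illness
        + _covariate_lp(cfg.covariate_effects.get("transfer", {}), cov)
    )
    transfer = rng.random(n) < p_tr
    zeros = np.zeros(n, dtype=bool)
    emit(active, 0, transfer, illness, zeros, zeros)

    prev_illness = illness.copy()
    prev_transfer = transfer.copy()
    prev_cov = cov

    for t in range(1, cfg.n_periods_max + 1):
        if not active.any():
            break
        # events in window t, driven by window t-1
        lp = {
            key: cfg.beta_transfer[key] * prev_transfer
            + cfg.gamma_illness[key] * prev_illness
            + cfg.gamma_frailty[key] * frailty
            + _covariate_lp(cfg.covariate_effects.get(key, {}), prev_cov)
            for key in ("physical", "cognitive", "death")
        }
        u_death = rng.random(n)
        u_disch = rng.random(n)
        u_phys = rng.random(n)
        u_cog = rng.random(n)
        died = active & (u_death < _grouped_ph_prob(cfg.baseline_hazards["death"], lp["death"]))
        discharged = active & ~died & (u_disch < cfg.p_discharge)
        survivors = active & ~died & ~discharged
        onset_phys = survivors & ~perm_phys & (
            u_phys < _grouped_ph_prob(cfg.baseline_hazards["physical"], lp["physical"])
        )
        onset_cog = survivors & ~perm_cog & (
            u_cog < _grouped_ph_prob(cfg.baseline_hazards["cognitive"], lp["cognitive"])
        )

        # scale evolution for survivors (impairment states absorbing)
        p_chess_up = expit(
            -1.6
            + cfg.chess_feedback_transfer * prev_transfer
            + cfg.chess_feedback_illness * prev_illness
        )
        up = rng.random(n) < p_chess_up
        down = rng.random(n) < 0.25
        chess = np.where(survivors, np.clip(chess + up - down, 0, 5), chess)

        walk_up = rng.random(n) < 0.10
        walk_dn = rng.random(n) < 0.05
        adl_new = np.clip(adl + walk_up - walk_dn, 0, 5)
        adl = np.where(survivors & ~perm_phys, adl_new, adl)
        perm_phys = perm_phys | onset_phys
        adl = np.where(onset_phys, 6, adl)

        walk_up = rng.random(n) < 0.08
        walk_dn = rng.random(n) < 0.04
        cps_new = np.clip(cps + walk_up - walk_dn, 0, 4)
        cps = np.where(survivors & ~perm_cog, cps_new, cps)
        perm_cog = perm_cog | onset_cog
        cps = np.where(onset_cog, 5, cps)

        # current-period illness, symptoms and transfer for survivors
        illness = survivors & (rng.random(n) < expit(logit(cfg.p_illness) + frailty))
        fell = survivors & (rng.random(n) < expit(-1.8 + 0.3 * (adl >= 4)))
        wchange = survivors & (rng.random(n) < np.clip(0.08 + 0.15 * illness, 0.0, 1.0))
        cov = _centered_covariates(age, sex, adl, chess, comorb, fell, wchange)
        p_tr = expit(
            logit(theta)
            + cfg.gamma_illness_transfer * illness
            + _covariate_lp(cfg.covariate_effects.get("transfer", {}), cov)
        )
        transfer = survivors & (rng.random(n) < p_tr)

        emit(died, t, np.zeros(n, dtype=bool), np.zeros(n, dtype=bool), died, zeros)
        emit(discharged, t, np.zeros(n, dtype=bool), np.zeros(n, dtype=bool), zeros, discharged)
        emit(survivors, t, transfer, illness, zeros, zeros)

        active = survivors
        prev_illness = illness.copy()
        prev_transfer = transfer.copy()
        prev_cov = cov

    assessments = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["resident_id", "period_index"], kind="mergesort")
        .reset_index(drop=True)
    )[ASSESSMENT_COLUMNS]
    truth_table = (
        pd.concat(truth_rows, ignore_index=True)
        .sort_values(["resident_id", "period_index"], kind="mergesort")
        .reset_index(drop=True)
    )[TRUTH_COLUMNS]

    truth = TruthTable(
        table=truth_table,
        home_theta=pd.DataFrame(
            {"home_id": [h.home_id for h in homes], "theta": theta_by_home}
        ),
        true_log_hr={f"transfer_{k}": v for k, v in cfg.beta_transfer.items()},
        config_json=cfg.to_json(),
    )
    return SimulatedCohort(assessments=assessments, home_history=home_history, truth=truth)


def simulate(config: SimulationConfig) -> SimulatedCohort:
    """Convenience wrapper: homes + cohort in one call."""
    return simulate_cohort(config, simulate_homes(config))
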