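"""End-to-end orchestration: simulate/load, build, estimate, report.

Every output file is plain delimited text carrying a provenance header
(configuration hash and seed) so a run is reproducible byte-for-byte from
its configuration. Estimator failures are isolated per outcome-estimator
cell: the pipeline continues and records the reason.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import incidence as incidence_mod
from . import io as io_mod
from . import iv as iv_mod
from . import msm as msm_mod
from .config import SimulationConfig
from .simulate import simulate as run_simulation
from .results import HazardEstimate

log = logging.getLogger("ltctransfer")

ALL_ESTIMATORS = ("crude", "extended_cox", "msm", "iv")

SUBGROUP_DEFINITIONS: dict[str, list[tuple[str, Any]]] = {
    "age": [
        ("age<80", lambda b: b["age_at_admission"] < 80),
        ("age80-89", lambda b: (b["age_at_admission"] >= 80) & (b["age_at_admission"] < 90)),
        ("age>=90", lambda b: b["age_at_admission"] >= 90),
    ],
    "adl": [
        ("adl<=2", lambda b: b["adl_hierarchy"] <= 2),
        ("2<adl<=4", lambda b: (b["adl_hierarchy"] > 2) & (b["adl_hierarchy"] <= 4)),
        ("adl=5", lambda b: b["adl_hierarchy"] == 5),
    ],
    "cps": [
        ("cps<=2", lambda b: b["cps"] <= 2),
        ("2<cps<=4", lambda b: (b["cps"] > 2) & (b["cps"] <= 4)),
        ("cps=5", lambda b: b["cps"] == 5),
    ],
}

MIN_SUBGROUP_EVENTS = 10


@dataclass
class AnalysisConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    outcomes: tuple[str, ...] = ("physical", "cognitive", "mortality")
    estimators: tuple[str, ...] = ALL_ESTIMATORS
    truncation: tuple[float, float] | None = (1.0, 99.0)
    iv_ci_method: str = "cluster_robust"
    n_boot: int = 500
    cohort_path: str | None = None  # load instead of simulate
    home_history_path: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.outcomes) - set(cohort_mod.OUTCOME_EVENT_CODE)
        if bad:
            raise ValueError(f"unknown outcomes: {sorted(bad)}")
        bad = set(self.estimators) - set(ALL_ESTIMATORS)
        if bad:
            raise ValueError(f"unknown estimators: {sorted(bad)}")

    @property
    def seed(self) -> int:
        return self.simulation.seed

    def provenance(self) -> dict[str, Any]:
        return {"config_hash": self.simulation.hash(), "seed": self.seed, "version": "0.1.0"}

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig.from_dict(raw.pop("simulation", {}))
        for key in ("outcomes", "estimators"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if raw.get("truncation") is not None and "truncation" in raw:
            raw["truncation"] = tuple(raw["truncation"])
        return cls(simulation=sim, **raw)


@dataclass
class ResultsBundle:
    cells: dict[tuple[str, str], HazardEstimate] = field(default_factory=dict)
    failures: dict[tuple[str, str], str] = field(default_factory=dict)
    incidence: pd.DataFrame | None = None
    baseline: pd.DataFrame | None = None
    eligibility: dict[str, cohort_mod.EligibilityReport] = field(default_factory=dict)
    weight_diagnostics: dict[str, pd.DataFrame] = field(default_factory=dict)
    iv_diagnostics: dict | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def estimates_table(self) -> pd.DataFrame:
        """Forest-plot data: one row per populated outcome-estimator cell."""
        rows = [est.to_dict() for est in self.cells.values()]
        for (outcome, estimator), reason in self.failures.items():
            rows.append({"estimator": estimator, "outcome": outcome, "failed": reason})
        return pd.DataFrame(rows)


def _load_or_simulate(config: AnalysisConfig):
    if config.cohort_path is not None:
        if not os.path.exists(config.cohort_path):
            raise FileNotFoundError(f"cohort file not found: {config.cohort_path}")
        cohort = io_mod.read_cohort(config.cohort_path)
        if config.home_history_path and os.path.exists(config.home_history_path):
            home_history = io_mod.read_home_history(config.home_history_path)
        else:
            raise FileNotFoundError(
                f"home history file not found: {config.home_history_path}"
            )
        return cohort, home_history, None
    simulated = run_simulation(config.simulation)
    return simulated.assessments, simulated.home_history, simulated.truth


def _estimate_cell(
    estimator: str,
    outcome: str,
    pp: pd.DataFrame,
    cohort: pd.DataFrame,
    home_history: pd.DataFrame,
    config: AnalysisConfig,
    bundle: ResultsBundle | None = None,
) -> HazardEstimate:
    if estimator == "crude":
        return msm_mod.fit_crude_cox(pp, outcome)
    if estimator == "extended_cox":
        return msm_mod.fit_extended_cox(pp, outcome)
    if estimator == "msm":
        spec = msm_mod.WeightModelSpec(truncation=config.truncation)
        weights = msm_mod.estimate_weights(pp, spec)
        if bundle is not None:
            bundle.weight_diagnostics[outcome] = weights.diagnostics()
        return msm_mod.fit_msm(pp, weights, outcome, spec)
    if estimator == "iv":
        ivfit = iv_mod.fit_iv(
            pp,
            cohort,
            home_history,
            outcome,
            ci_method=config.iv_ci_method,
            n_boot=config.n_boot,
            seed=config.seed,
        )
        est = ivfit.estimate
        est.extra["residual_coef"] = ivfit.residual_coef
        return est
    raise ValueError(f"unknown estimator {estimator!r}")


def run_pipeline(config: AnalysisConfig, outdir: str | None = None) -> ResultsBundle:
    """Run every requested outcome x estimator cell and assemble the bundle."""
    cohort, home_history, truth = _load_or_simulate(config)
    bundle = ResultsBundle(provenance=config.provenance())
    log.info("cohort: %d rows, %d residents", len(cohort), cohort["resident_id"].nunique())

    pp_by_outcome: dict[str, pd.DataFrame] = {}
    for outcome in config.outcomes:
        eligible, report = cohort_mod.apply_eligibility(cohort, outcome)
        bundle.eligibility[outcome] = report
        pp = cohort_mod.build_person_periods(
            eligible, outcome, n_periods_max=config.simulation.n_periods_max
        )
        pp_by_outcome[outcome] = pp
        log.info("%s: %d person-periods, %d events", outcome, len(pp), pp["event"].sum())

    bundle.incidence = incidence_mod.incidence_table(pp_by_outcome, cohort)
    bundle.baseline = incidence_mod.baseline_table(cohort)
    if "iv" in config.estimators:
        try:
            instrument = iv_mod.compute_instrument(cohort, home_history)
            bundle.iv_diagnostics = iv_mod.instrument_diagnostics(cohort, instrument)
        except ValueError as exc:
            bundle.iv_diagnostics = {"error": str(exc)}

    for outcome in config.outcomes:
        for estimator in config.estimators:
            try:
                bundle.cells[(outcome, estimator)] = _estimate_cell(
                    estimator, outcome, pp_by_outcome[outcome], cohort, home_history,
                    config, bundle,
                )
            except Exception as exc:  # isolate per-cell failures
                log.warning("cell (%s, %s) failed: %s", outcome, estimator, exc)
                bundle.failures[(outcome, estimator)] = str(exc)

    if outdir is not None:
        emit_tables(bundle, outdir, cohort=cohort, home_history=home_history,
                    truth=truth, pp_by_outcome=pp_by_outcome)
    return bundle


def emit_tables(
    bundle: ResultsBundle,
    outdir: str,
    cohort: pd.DataFrame | None = None,
    home_history: pd.DataFrame | None = None,
    truth=None,
    pp_by_outcome: dict[str, pd.DataFrame] | None = None,
) -> None:
    """Write all artifacts as delimited text with provenance headers."""
    os.makedirs(outdir, exist_ok=True)
    prov = bundle.provenance
    header = [f"config_hash={prov.get('config_hash')} seed={prov.get('seed')}"]

    def path(name: str) -> str:
        return os.path.join(outdir, name)

    if cohort is not None:
        io_mod.write_cohort(cohort, path("cohort.csv"), header)
    if home_history is not None:
        io_mod.write_home_history(home_history, path("homes.csv"), header)
    if truth is not None:
        io_mod.write_truth(truth.table, path("truth.csv"),
                           header + [f"true_log_hr={json.dumps(truth.true_log_hr, sort_keys=True)}"])
    for outcome, pp in (pp_by_outcome or {}).items():
        io_mod.write_table(pp, path(f"pp_{outcome}.csv"), header)
    if bundle.baseline is not None:
        io_mod.write_table(bundle.baseline, path("table1.csv"), header)
    if bundle.incidence is not None:
        io_mod.write_table(bundle.incidence, path("table2.csv"), header)
    io_mod.write_table(bundle.estimates_table(), path("estimates.csv"), header)
    for outcome, diag in bundle.weight_diagnostics.items():
        io_mod.write_table(diag, path(f"weights_{outcome}.csv"), header)
    if bundle.iv_diagnostics is not None and "error" not in bundle.iv_diagnostics:
        io_mod.write_table(bundle.iv_diagnostics["baseline_smd"], path("iv_balance.csv"), header)
        io_mod.write_table(
            bundle.iv_diagnostics["quintile_incidence"], path("iv_quintiles.csv"), header
        )
    with open(path("eligibility.json"), "w") as fh:
        json.dump(
            {k: v.to_dict() for k, v in bundle.eligibility.items()},
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    summary = {
        "provenance": prov,
        "cells": {f"{o}/{e}": est.to_dict() for (o, e), est in bundle.cells.items()},
        "failures": {f"{o}/{e}": r for (o, e), r in bundle.failures.items()},
    }
    if bundle.iv_diagnostics is not None:
        summary["iv_relevance_wald_z"] = bundle.iv_diagnostics.get("relevance_wald_z")
    with open(path("results.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def subgroup_analysis(
    config: AnalysisConfig, stratifier: str
) -> pd.DataFrame:
    """Re-run the estimator set within baseline strata of one stratifier.

    Strata are defined on admission (period-0) values; strata with fewer
    than 10 events for an outcome are flagged and skipped, not fatal.
    """
    if stratifier not in SUBGROUP_DEFINITIONS:
        raise ValueError(
            f"unknown stratifier {stratifier!r}; choose from {sorted(SUBGROUP_DEFINITIONS)}"
        )
    cohort, home_history, _ = _load_or_simulate(config)
    base = cohort[cohort["period_index"] == 0]
    rows = []
    for label, selector in SUBGROUP_DEFINITIONS[stratifier]:
        ids = set(base.loc[selector(base), "resident_id"])
        sub = cohort[cohort["resident_id"].isin(ids)]
        if not len(sub):
            rows.append({"stratum": label, "status": "empty"})
            continue
        for outcome in config.outcomes:
            eligible, _ = cohort_mod.apply_eligibility(sub, outcome)
            if not len(eligible):
                rows.append({"stratum": label, "outcome": outcome, "status": "empty"})
                continue
            pp = cohort_mod.build_person_periods(
                eligible, outcome, n_periods_max=config.simulation.n_periods_max
            )
            n_events = int(pp["event"].sum())
            if n_events < MIN_SUBGROUP_EVENTS:
                rows.append(
                    {
                        "stratum": label,
                        "outcome": outcome,
                        "status": f"skipped (<{MIN_SUBGROUP_EVENTS} events)",
                        "n_events": n_events,
                    }
                )
                continue
            for estimator in config.estimators:
                try:
                    est = _estimate_cell(
                        estimator, outcome, pp, sub, home_history, config
                    )
                    rows.append(
                        {"stratum": label, "status": "ok", **est.to_dict()}
                    )
                except Exception as exc:
                    rows.append(
                        {
                            "stratum": label,
                            "outcome": outcome,
                            "estimator": estimator,
                            "status": f"failed: {exc}",
                        }
                    )
    return pd.DataFrame(rows)
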