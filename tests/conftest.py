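"""Shared fixtures: one small simulated cohort reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ltctransfer as lt

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> lt.SimulationConfig:
    return lt.SimulationConfig(n_homes=12, residents_per_home=40, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return lt.simulate(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_sim) -> pd.DataFrame:
    return small_sim.assessments


@pytest.fixture(scope="session")
def pp_mortality(small_cohort, small_config) -> pd.DataFrame:
    eligible, _ = lt.apply_eligibility(small_cohort, "mortality")
    return lt.build_person_periods(
        eligible, "mortality", n_periods_max=small_config.n_periods_max
    )


@pytest.fixture(scope="session")
def pp_physical(small_cohort, small_config) -> pd.DataFrame:
    eligible, _ = lt.apply_eligibility(small_cohort, "physical")
    return lt.build_person_periods(
        eligible, "physical", n_periods_max=small_config.n_periods_max
    )


def toy_cox_data(seed: int = 3, n: int = 300, n_periods: int = 6) -> pd.DataFrame:
    """Hand-rolled counting-process data independent of the simulator."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        x1 = rng.binomial(1, 0.4)
        x2 = rng.normal()
        cluster = i % 12
        for k in range(n_periods):
            h = 0.05 * np.exp(0.6 * x1 - 0.3 * x2)
            event = rng.random() < min(h, 0.95)
            rows.append(
                {
                    "id": i,
                    "cluster": cluster,
                    "start_day": 92 * k,
                    "stop_day": 92 * (k + 1),
                    "event": int(event),
                    "x1": x1,
                    "x2": x2,
                    "w": 1.0,
                }
            )
            if event:
                break
    return pd.DataFrame(rows)
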