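"""Configuration objects for the simulator and the analysis pipeline.

The simulator emulates the longitudinal structure of RAI-MDS-2.0-style
long-term-care (LTC) assessment data: quarterly (92-day) assessments from
admission, facility-level variation in the propensity to transfer residents
to hospital, a latent acute-illness process that confounds transfer and
outcomes, and known true causal effects of transfer on permanent physical
impairment, permanent cognitive impairment and death.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

OUTCOMES = ("physical", "cognitive", "mortality")

#: outcome key used inside the generator for event hazards
EVENT_KEYS = ("physical", "cognitive", "death")


class ConfigurationError(ValueError):
    """Raised when a configuration value is outside its admissible range."""


def _default_beta_transfer() -> dict[str, float]:
    # True causal log-HRs of transfer on each outcome. Defaults mirror the
    # qualitative pattern the analysis is designed to detect: a modest,
    # possibly null effect on impairments and a protective effect on death.
    return {"physical": 0.18, "cognitive": -0.15, "death": -0.56}


def _default_gamma_illness() -> dict[str, float]:
    # Log-HRs of the latent acute illness on each outcome (the unmeasured
    # confounding pathway). Death is strongly illness-mediated: most deaths
    # occur in the window after an acute episode, which is what concentrates
    # transfers shortly before death.
    return {"physical": 1.2, "cognitive": 1.0, "death": 5.6}


def _default_gamma_frailty() -> dict[str, float]:
    # Direct (chronic) log-HRs of the latent frailty on each outcome, on top
    # of its effect through the acute-illness probability. This is what keeps
    # the hazards of frail residents mildly elevated even in illness-free
    # windows, so the exposed-vs-unexposed window contrast stays finite.
    return {"physical": 0.15, "cognitive": 0.15, "death": 0.05}


def _default_baseline_hazards() -> dict[str, float]:
    # Per-92-day event probabilities at reference covariates, no illness,
    # no transfer, zero frailty. Deaths at reference are rare: mortality is
    # driven almost entirely by the acute-illness pathway.
    return {"physical": 0.005, "cognitive": 0.005, "death": 0.001}


def _default_covariate_effects() -> dict[str, dict[str, float]]:
    # Measured-confounder effects (log-odds for transfer, log-HR for events).
    # ``chess`` is the time-varying health-instability scale; ``age_c`` is
    # (age - 85) in years; ``fell_30d`` a recent-fall flag.
    return {
        "transfer": {"chess": 0.25, "fell_30d": 0.30},
        "physical": {"chess": 0.10},
        "cognitive": {"chess": 0.10},
        "death": {"chess": 0.20, "age_c": 0.02},
    }


@dataclass
class SimulationConfig:
    """Parameters of the discrete-time LTC cohort generator.

    All hazards live on the 92-day assessment grid: ``baseline_hazards`` are
    per-period event probabilities, ``beta_transfer``/``gamma_illness`` are
    log hazard ratios applied multiplicatively on the grouped-hazard scale,
    and ``theta_range`` spans the per-period transfer propensities of the
    simulated homes (the preference-based instrument).
    """

    n_homes: int = 50
    residents_per_home: int = 40
    n_periods_max: int = 20  # 20 x 92 days ~ five years of follow-up
    seed: int = 0
    # healthy-state per-period transfer propensities across homes; the same
    # home effect also shifts the (much higher) probability of transferring
    # an acutely ill resident, which is where most transfers originate
    theta_range: tuple[float, float] = (0.002, 0.08)
    beta_transfer: dict[str, float] = field(default_factory=_default_beta_transfer)
    gamma_illness_transfer: float = 7.0
    gamma_illness: dict[str, float] = field(default_factory=_default_gamma_illness)
    gamma_frailty: dict[str, float] = field(default_factory=_default_gamma_frailty)
    baseline_hazards: dict[str, float] = field(default_factory=_default_baseline_hazards)
    covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=_default_covariate_effects
    )
    p_illness: float = 0.05
    frailty_sd: float = 1.8
    p_discharge: float = 0.01
    # feedback of last period's transfer / illness on the probability that
    # the CHESS instability score rises next period (what makes CHESS a
    # time-varying confounder affected by past exposure)
    chess_feedback_transfer: float = 0.8
    chess_feedback_illness: float = 0.8

    def __post_init__(self) -> None:
        self.theta_range = tuple(self.theta_range)  # type: ignore[assignment]
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.n_homes < 1:
            raise ConfigurationError("n_homes must be >= 1")
        if self.residents_per_home < 1:
            raise ConfigurationError("residents_per_home must be >= 1")
        if self.n_periods_max < 1:
            raise ConfigurationError("n_periods_max must be >= 1")
        lo, hi = self.theta_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError(
                f"theta_range must satisfy 0 < lo <= hi < 1, got {self.theta_range!r}"
            )
        for name, p in (("p_illness", self.p_illness), ("p_discharge", self.p_discharge)):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        for key in EVENT_KEYS:
            h = self.baseline_hazards.get(key)
            if h is None:
                raise ConfigurationError(f"baseline_hazards missing key {key!r}")
            if not 0.0 <= h <= 1.0:
                raise ConfigurationError(
                    f"baseline_hazards[{key!r}] must be a probability in [0, 1], got {h}"
                )
            if key not in self.beta_transfer:
                raise ConfigurationError(f"beta_transfer missing key {key!r}")
            if key not in self.gamma_illness:
                raise ConfigurationError(f"gamma_illness missing key {key!r}")
            if key not in self.gamma_frailty:
                raise ConfigurationError(f"gamma_frailty missing key {key!r}")
        if self.frailty_sd < 0:
            raise ConfigurationError("frailty_sd must be >= 0")

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["theta_range"] = list(self.theta_range)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "theta_range" in d:
            d["theta_range"] = tuple(d["theta_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    # -- named study conditions -----------------------------------------
    @classmethod
    def paper_like(cls, **overrides: Any) -> "SimulationConfig":
        """The documented headline configuration.

        Acute illness is rare but strongly lethal and almost always triggers
        a transfer, so transfers cluster shortly before death and the crude
        ever-vs-never mortality contrast is heavily confounded upward. The
        planted transfer effect on death is truly protective and the effects
        on the impairments are near-null, while the home-propensity spread
        keeps the preference instrument strong. Sized near the motivating
        cohort (60,000 residents in 400 homes) so the control-function
        confidence intervals are informative.
        """
        base: dict[str, Any] = dict(
            n_homes=400,
            residents_per_home=150,
            beta_transfer={"physical": 0.18, "cognitive": -0.15, "death": -0.56},
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def measured_confounding(cls, **overrides: Any) -> "SimulationConfig":
        """Confounding only through measured covariates (no latent-illness
        pathway): the setting in which the marginal structural model is
        consistent while the crude estimate is not."""
        base: dict[str, Any] = dict(
            theta_range=(0.05, 0.35),
            gamma_illness_transfer=0.0,
            gamma_illness={"physical": 0.0, "cognitive": 0.0, "death": 0.0},
            gamma_frailty={"physical": 0.0, "cognitive": 0.0, "death": 0.0},
            beta_transfer={"physical": 0.10, "cognitive": 0.0, "death": 0.30},
            baseline_hazards={"physical": 0.010, "cognitive": 0.010, "death": 0.030},
            covariate_effects={
                "transfer": {"chess": 0.45, "fell_30d": 0.30},
                "physical": {"chess": 0.10},
                "cognitive": {"chess": 0.10},
                "death": {"chess": 0.35, "age_c": 0.02},
            },
            # no transfer->CHESS feedback here: CHESS is a pure time-varying
            # confounder, not a mediator, so the planted window-level log-HR
            # is also the total causal effect the weighted fit should recover
            chess_feedback_transfer=0.0,
            chess_feedback_illness=0.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def latent_confounding(cls, **overrides: Any) -> "SimulationConfig":
        """Moderate unmeasured (latent-illness) confounding with a truly
        protective transfer effect on death: the setting in which the
        control-function estimator is consistent while crude and
        covariate-adjusted estimates are biased upward."""
        base: dict[str, Any] = dict(
            theta_range=(0.05, 0.35),
            gamma_illness_transfer=1.5,
            gamma_illness={"physical": 0.3, "cognitive": 0.3, "death": 1.0},
            gamma_frailty={"physical": 0.0, "cognitive": 0.0, "death": 0.0},
            beta_transfer={"physical": 0.0, "cognitive": 0.0, "death": -0.5},
            baseline_hazards={"physical": 0.008, "cognitive": 0.008, "death": 0.020},
            p_illness=0.15,
            frailty_sd=0.8,
            # as in measured_confounding: no transfer->CHESS feedback, so the
            # planted log-HR is the total effect the instrument should recover
            chess_feedback_transfer=0.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def null_effects(cls, **overrides: Any) -> "SimulationConfig":
        """No causal transfer effect, no confounding of any kind."""
        base: dict[str, Any] = dict(
            theta_range=(0.05, 0.35),
            gamma_illness_transfer=0.0,
            gamma_illness={"physical": 0.0, "cognitive": 0.0, "death": 0.0},
            gamma_frailty={"physical": 0.0, "cognitive": 0.0, "death": 0.0},
            beta_transfer={"physical": 0.0, "cognitive": 0.0, "death": 0.0},
            baseline_hazards={"physical": 0.010, "cognitive": 0.010, "death": 0.030},
            covariate_effects={
                "transfer": {},
                "physical": {},
                "cognitive": {},
                "death": {},
            },
            chess_feedback_transfer=0.0,
            chess_feedback_illness=0.0,
        )
        base.update(overrides)
        return cls(**base)
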