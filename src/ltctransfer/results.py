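"""Result containers shared by the estimators and the reporting layer."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import math

Z95 = 1.959963984540054


@dataclass
class HazardEstimate:
    """A single hazard-ratio estimate for one outcome and one estimator."""

    estimator: str  # crude | extended_cox | msm | iv
    outcome: str  # physical | cognitive | mortality
    log_hr: float
    se_model: float
    se_robust: float | None
    ci_low: float
    ci_high: float
    n_events: int
    converged: bool
    extra: dict[str, Any] = field(default_factory=dict)

    @property
    def hr(self) -> float:
        return math.exp(self.log_hr)

    def to_dict(self) -> dict[str, Any]:
        return {
            "estimator": self.estimator,
            "outcome": self.outcome,
            "log_hr": self.log_hr,
            "hr": self.hr,
            "se_model": self.se_model,
            "se_robust": self.se_robust,
            "hr_ci_low": self.ci_low,
            "hr_ci_high": self.ci_high,
            "n_events": self.n_events,
            "converged": self.converged,
            **{f"extra_{k}": v for k, v in self.extra.items()},
        }


def estimate_from_fit(fit, estimator: str, outcome: str, name: str = "exposed", **extra) -> HazardEstimate:
    """Build a :class:`HazardEstimate` for one coefficient of a Cox fit."""
    b = fit.coef(name)
    se = fit.coef_se(name)
    rse = None
    if fit.vcov_robust is not None:
        rse = float(fit.robust_se[fit.covariates.index(name)])
    return HazardEstimate(
        estimator=estimator,
        outcome=outcome,
        log_hr=b,
        se_model=float(fit.model_se[fit.covariates.index(name)]),
        se_robust=rse,
        ci_low=math.exp(b - Z95 * se),
        ci_high=math.exp(b + Z95 * se),
        n_events=fit.n_events,
        converged=fit.converged,
        extra=extra,
    )
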