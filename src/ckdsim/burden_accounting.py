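"""QALY and cost accrual for the CKD burden model.

Utilities: perfect health 1, pre-end-stage CKD (stages I-IV) 0.81, ESRD
0.658, death 0. Costs (yuan, annual unless noted): outpatient care 4,159
for stages I-IV and 107,209 for stage V; ACEI/ARB treatment 30/week charged
to treated pre-end-stage person-years; screening tests 4 (urinalysis) + 8
(blood creatinine) per screen. Costs are discounted at 5%/year; QALYs are
undiscounted by default (the engine exposes a switch).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import TYPE_CHECKING

from .errors import DomainError, EmptyInputError, ParameterError
from .states import PRE_ESRD_STATES, State

if TYPE_CHECKING:  # pragma: no cover
    from .simulation_engine import ScenarioComparison

__all__ = [
    "UtilityParams",
    "CostParams",
    "discount",
    "annual_cost",
    "annual_qaly",
    "summarize_economics",
    "to_million",
    "WEEKS_PER_YEAR",
]

WEEKS_PER_YEAR = 52


@dataclass(frozen=True)
class UtilityParams:
    """Health-state utilities (QALY weights per year of occupancy)."""

    u_at_risk: float = 1.0
    u_ckd: float = 0.81
    u_esrd: float = 0.658
    u_dead: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.u_dead <= self.u_esrd <= self.u_ckd <= self.u_at_risk <= 1.0:
            raise ParameterError(
                "utilities must satisfy 0 <= u_dead <= u_esrd <= u_ckd "
                f"<= u_at_risk <= 1, got {self}"
            )

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "UtilityParams":
        return cls(**d)


@dataclass(frozen=True)
class CostParams:
    """Unit costs in yuan and the annual cost discount rate."""

    c_outpatient_ckd: float = 4159.0
    c_outpatient_esrd: float = 107209.0
    c_treatment_weekly: float = 30.0
    c_screen_urinalysis: float = 4.0
    c_screen_creatinine: float = 8.0
    discount_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "c_outpatient_ckd",
            "c_outpatient_esrd",
            "c_treatment_weekly",
            "c_screen_urinalysis",
            "c_screen_creatinine",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ParameterError(
                f"discount_rate must be in [0, 1), got {self.discount_rate}"
            )

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CostParams":
        return cls(**d)


def discount(amount: float, years_from_start: float, rate: float) -> float:
    """Present value of ``amount`` accrued ``years_from_start`` years in:
    ``amount / (1 + rate) ** years_from_start``."""
    if years_from_start < 0:
        raise ParameterError(f"years_from_start must be >= 0, got {years_from_start}")
    return amount / (1.0 + rate) ** years_from_start


def annual_cost(state: State, treated: bool, params: CostParams) -> float:
    """Undiscounted yuan accrued by one person-year in ``state``.

    Pre-end-stage CKD years cost the stage I-IV outpatient amount, plus a
    year of weekly ACEI/ARB therapy if ``treated``; ESRD years cost the
    stage V outpatient amount; AT_RISK and DEAD years cost nothing.
    Screening costs are charged separately at screening events.
    """
    if not isinstance(state, State):
        raise DomainError(f"unknown state {state!r}")
    if state is State.AT_RISK or state is State.DEAD:
        return 0.0
    if state in PRE_ESRD_STATES:
        cost = params.c_outpatient_ckd
        if treated:
            cost += WEEKS_PER_YEAR * params.c_treatment_weekly
        return cost
    return params.c_outpatient_esrd  # ESRD


def annual_qaly(state: State, params: UtilityParams) -> float:
    """QALY-years accrued by one full person-year in ``state``."""
    if not isinstance(state, State):
        raise DomainError(f"unknown state {state!r}")
    if state is State.AT_RISK:
        return params.u_at_risk
    if state in PRE_ESRD_STATES:
        return params.u_ckd
    if state is State.ESRD:
        return params.u_esrd
    return params.u_dead


def to_million(yuan: float) -> int:
    """Render yuan as whole million yuan, rounding half up (report layer)."""
    return int(
        (Decimal(str(yuan)) / Decimal(1_000_000)).quantize(
            Decimal(1), rounding=ROUND_HALF_UP
        )
    )


def summarize_economics(comparison: "ScenarioComparison") -> dict:
    """Horizon summary of a paired intervention/control run.

    Returns per-year savings (control total cost minus intervention total
    cost, yuan), their arithmetic mean over the horizon (yuan and rounded
    million yuan), and the final-year cumulative-ESRD comparison: the
    intervention count as a percentage of the control count, and the
    absolute reduction in end-stage cases.
    """
    if not comparison.intervention or not comparison.control:
        raise EmptyInputError("comparison has no simulated years")
    savings = [
        c.cost_total - i.cost_total
        for c, i in zip(comparison.control, comparison.intervention)
    ]
    mean_savings = sum(savings) / len(savings)
    cum_int = comparison.cumulative_esrd("intervention")[-1]
    cum_ctl = comparison.cumulative_esrd("control")[-1]
    ratio_pct = 100.0 * cum_int / cum_ctl if cum_ctl > 0 else 100.0
    return {
        "savings_per_year": savings,
        "mean_annual_savings": mean_savings,
        "mean_annual_savings_million": to_million(mean_savings),
        "final_year_esrd_intervention": cum_int,
        "final_year_esrd_control": cum_ctl,
        "final_year_esrd_ratio_pct": round(ratio_pct, 2),
        "esrd_reduction": cum_ctl - cum_int,
    }
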