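"""Screening-intervention strategies.

A strategy is an eligibility predicate over (age, hypertension, diabetes),
a schedule (screen at baseline only, or every year), unit test costs, and a
participation proportion. The five built-in strategies target: the
hypertension group; the diabetes group; hypertension or diabetes; everyone
aged 65 and older; and the union of all three markers.

Screening is a perfect test (sensitivity = specificity = 1): every
screened pre-end-stage CKD individual is detected and started on ACEI/ARB
management in the same year. AT_RISK and ESRD individuals accrue the
screening cost without changing state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .errors import ConfigurationError, ParameterError
from .states import State
from .synthetic_population import Individual

__all__ = [
    "Strategy",
    "builtin_strategies",
    "get_strategy",
    "apply_screening",
    "CRITERIA",
]

#: Recognized eligibility criteria; a strategy matches if ANY of its
#: criteria hold for the individual.
CRITERIA = ("hypertension", "diabetes", "age65")

#: Age threshold (in current, aged years) for the "age65" criterion.
AGE_THRESHOLD = 65


@dataclass(frozen=True)
class Strategy:
    """One screening-intervention scenario."""

    name: str
    criteria: frozenset[str]
    schedule: str = "baseline_only"  # or "annual"
    cost_urinalysis: float = 4.0
    cost_creatinine: float = 8.0
    participation: float = 1.0

    def __post_init__(self) -> None:
        unknown = set(self.criteria) - set(CRITERIA)
        if unknown:
            raise ConfigurationError(f"unknown eligibility criteria: {sorted(unknown)}")
        if self.schedule not in ("baseline_only", "annual"):
            raise ConfigurationError(
                f"schedule must be 'baseline_only' or 'annual', got {self.schedule!r}"
            )
        if self.cost_urinalysis < 0 or self.cost_creatinine < 0:
            raise ParameterError("screening test costs must be >= 0")
        if not 0.0 <= self.participation <= 1.0:
            raise ParameterError(
                f"participation must be in [0, 1], got {self.participation}"
            )

    @property
    def cost_per_screen(self) -> float:
        return self.cost_urinalysis + self.cost_creatinine

    def is_eligible(self, individual: Individual) -> bool:
        """Eligibility at the time of a screening event (current age)."""
        return (
            ("hypertension" in self.criteria and individual.hypertension)
            or ("diabetes" in self.criteria and individual.diabetes)
            or ("age65" in self.criteria and individual.age >= AGE_THRESHOLD)
        )

    def with_costs_scaled(self, factor: float) -> "Strategy":
        """Copy with both unit test costs scaled (sensitivity analysis)."""
        return replace(
            self,
            cost_urinalysis=self.cost_urinalysis * factor,
            cost_creatinine=self.cost_creatinine * factor,
        )


def builtin_strategies() -> list[Strategy]:
    """The five scenarios, in their canonical order."""
    return [
        Strategy("hypertension", frozenset({"hypertension"})),
        Strategy("diabetes", frozenset({"diabetes"})),
        Strategy("hypertension_diabetes", frozenset({"hypertension", "diabetes"})),
        Strategy("age65", frozenset({"age65"})),
        Strategy(
            "hypertension_diabetes_age65",
            frozenset({"hypertension", "diabetes", "age65"}),
        ),
    ]


def get_strategy(name: str, **overrides) -> Strategy:
    """Look up a built-in strategy by name, optionally overriding fields
    (schedule, unit costs, participation)."""
    for s in builtin_strategies():
        if s.name == name:
            return replace(s, **overrides) if overrides else s
    known = [s.name for s in builtin_strategies()]
    raise ConfigurationError(f"unknown strategy {name!r}; built-ins: {known}")


def apply_screening(
    cohort: Iterable[Individual],
    strategy: Strategy,
    year: int,
    seed: int = 0,
) -> tuple[list[Individual], float]:
    """Screen the cohort once in ``year`` under ``strategy`` (in place).

    Every eligible, participating, living individual accrues the per-screen
    cost; screened CKD_UNDETECTED / CKD_DIAGNOSED individuals move to
    CKD_TREATED. AT_RISK and ESRD individuals change cost only. A second
    application in the same year is a no-op (individuals remember their
    last screening year), so per-year costs are never double-charged.

    Returns the (mutated) cohort and the total undiscounted screening cost
    for the year. Participation below 1 selects individuals by a
    deterministic per-(seed, year) draw.
    """
    cohort = list(cohort)
    if strategy.participation <= 0.0:
        return cohort, 0.0

    if strategy.participation < 1.0:
        u = np.random.default_rng([seed, year, 977]).random(len(cohort))
        participates = u < strategy.participation
    else:
        participates = np.ones(len(cohort), dtype=bool)

    total_cost = 0.0
    for i, ind in enumerate(cohort):
        if not ind.is_alive() or not participates[i]:
            continue
        if ind.last_screened_year == year:
            continue
        if not strategy.is_eligible(ind):
            continue
        ind.last_screened_year = year
        total_cost += strategy.cost_per_screen
        if ind.state in (State.CKD_UNDETECTED, State.CKD_DIAGNOSED):
            ind.state = State.CKD_TREATED
    return cohort, total_cost
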