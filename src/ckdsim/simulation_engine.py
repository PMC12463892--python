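"""Annual-cycle micro-simulation engine.

Runs one scenario arm (with or without screening) over a closed cohort,
and paired intervention/control arms under common random numbers (CRN).

Cycle order, each simulated year: (1) screening, if scheduled; (2) one
annual state transition per living individual, drawn by inverse transform
from that individual's pre-allocated uniform for the year; (3) survivors
age by one year; (4) QALYs and discounted costs accrue for the state
occupied at the end of the cycle (individuals dying within the year accrue
nothing for that year — no half-cycle correction).

Random-number contract: a master seed yields one uniform per (individual,
year) from a per-year child stream, so paired arms consume identical draws
and extending the horizon never re-draws history. Combined with the
worst-outcome-first inverse-transform ordering, a treated individual's
death or ESRD onset under the intervention implies the same-or-worse
outcome under control for the same draw.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .burden_accounting import (
    CostParams,
    UtilityParams,
    annual_cost,
    annual_qaly,
    discount,
)
from .errors import ConsistencyError, ParameterError
from .screening_strategies import Strategy, apply_screening
from .states import SAMPLING_ORDER, STATE_INDEX, STATE_ORDER, State
from .synthetic_population import Individual
from .transition_model import (
    TransitionMatrix,
    TransitionParameters,
    build_transition_matrix,
)

__all__ = [
    "YearlyLedger",
    "ScenarioComparison",
    "run_arm",
    "run_paired",
    "expected_occupancy",
    "year_uniforms",
]

_DEAD_IDX = STATE_INDEX[State.DEAD]
_ESRD_IDX = STATE_INDEX[State.ESRD]
_TREATED_IDX = STATE_INDEX[State.CKD_TREATED]
_SAMPLING_IDX = np.array([STATE_INDEX[s] for s in SAMPLING_ORDER])


@dataclass
class YearlyLedger:
    """Per-year accounting for one scenario arm."""

    year: int
    state_counts: dict[State, int]
    new_esrd: int
    deaths: int
    qalys_total: float
    qalys_per_capita: float
    cost_total: float
    cost_components: dict[str, float] = field(default_factory=dict)


@dataclass
class ScenarioComparison:
    """Paired intervention/control ledgers plus derived deltas.

    All derived quantities are pure functions of the two ledger arrays.
    """

    strategy_name: str
    intervention: list[YearlyLedger]
    control: list[YearlyLedger]

    def _arm(self, arm: str) -> list[YearlyLedger]:
        if arm == "intervention":
            return self.intervention
        if arm == "control":
            return self.control
        raise ParameterError(f"arm must be 'intervention' or 'control', got {arm!r}")

    def cumulative_esrd(self, arm: str) -> list[int]:
        """Cumulative count of new end-stage cases through each year."""
        out, total = [], 0
        for ledger in self._arm(arm):
            total += ledger.new_esrd
            out.append(total)
        return out

    def cumulative_deaths(self, arm: str) -> list[int]:
        out, total = [], 0
        for ledger in self._arm(arm):
            total += ledger.deaths
            out.append(total)
        return out

    @property
    def esrd_reduction(self) -> list[int]:
        """Control-minus-intervention cumulative new-ESRD count per year."""
        ci = self.cumulative_esrd("intervention")
        cc = self.cumulative_esrd("control")
        return [c - i for c, i in zip(cc, ci)]

    @property
    def cost_savings(self) -> list[float]:
        """Control-minus-intervention discounted total cost per year (yuan)."""
        return [
            c.cost_total - i.cost_total
            for c, i in zip(self.control, self.intervention)
        ]

    @property
    def qaly_gain_per_capita(self) -> list[float]:
        return [
            i.qalys_per_capita - c.qalys_per_capita
            for c, i in zip(self.control, self.intervention)
        ]

    @property
    def final_year_esrd_ratio(self) -> float:
        """Final-year intervention cumulative ESRD as % of control."""
        ci = self.cumulative_esrd("intervention")[-1]
        cc = self.cumulative_esrd("control")[-1]
        return 100.0 * ci / cc if cc > 0 else 100.0

    @property
    def mean_annual_cost_savings(self) -> float:
        savings = self.cost_savings
        return sum(savings) / len(savings)


def year_uniforms(master_seed, year: int, n: int) -> np.ndarray:
    """The cohort's uniforms for one simulated year.

    Child-seeded by (master_seed, year) so paired arms share draws and
    horizon extension never perturbs earlier years.
    """
    if isinstance(master_seed, (list, tuple)):
        seed = [*master_seed, year]
    else:
        seed = [master_seed, year]
    return np.random.default_rng(seed).random(n)


def _screen_due(strategy: Optional[Strategy], year_index: int) -> bool:
    if strategy is None:
        return False
    return strategy.schedule == "annual" or year_index == 0


def run_arm(
    cohort: Sequence[Individual],
    params: TransitionParameters,
    strategy: Optional[Strategy],
    start_year: int,
    horizon: int,
    master_seed,
    utilities: Optional[UtilityParams] = None,
    costs: Optional[CostParams] = None,
    matrix: Optional[TransitionMatrix] = None,
    discount_qalys: bool = False,
) -> list[YearlyLedger]:
    """Simulate one arm for ``horizon`` years; returns one ledger per year.

    ``strategy=None`` is the no-intervention arm: no screening, and the
    transition matrix uses the untreated variant (treatment rows equal the
    diagnosed row). A ``matrix`` argument overrides the matrix built from
    ``params`` (used by the sensitivity analysis). The input cohort is
    never mutated.
    """
    if horizon < 1:
        raise ParameterError(f"horizon must be >= 1, got {horizon}")
    cohort = list(cohort)
    if not cohort:
        raise ParameterError("cohort must be non-empty")
    if all(not ind.is_alive() for ind in cohort):
        warnings.warn("cohort contains no living individuals", stacklevel=2)

    cohort = copy.deepcopy(cohort)
    n0 = len(cohort)
    utilities = utilities if utilities is not None else UtilityParams()
    costs = costs if costs is not None else CostParams()
    tm = (
        matrix
        if matrix is not None
        else build_transition_matrix(params, treated_variant=strategy is not None)
    )
    cum = tm.sampling_cumulative()  # (6, 6) thresholds in SAMPLING_ORDER

    u_vec = np.array([annual_qaly(s, utilities) for s in STATE_ORDER])
    outpatient_vec = np.array(
        [annual_cost(s, treated=False, params=costs) for s in STATE_ORDER]
    )
    treatment_annual = annual_cost(
        State.CKD_TREATED, treated=True, params=costs
    ) - annual_cost(State.CKD_TREATED, treated=False, params=costs)

    ledgers: list[YearlyLedger] = []
    for t in range(horizon):
        year = start_year + t

        screening_cost = 0.0
        if _screen_due(strategy, t):
            _, screening_cost = apply_screening(
                cohort, strategy, year, seed=_seed_scalar(master_seed)
            )

        states = np.array([STATE_INDEX[ind.state] for ind in cohort])
        u = year_uniforms(master_seed, year, n0)

        # Inverse-transform draw, worst destinations first.
        thresholds = cum[states]  # (n, 6)
        pos = (thresholds <= u[:, None]).sum(axis=1)
        np.clip(pos, 0, len(STATE_ORDER) - 1, out=pos)
        new_states = _SAMPLING_IDX[pos]
        new_states[states == _DEAD_IDX] = _DEAD_IDX  # absorbing, skip draw

        new_esrd = int(np.sum((new_states == _ESRD_IDX) & (states != _ESRD_IDX)))
        deaths = int(np.sum((new_states == _DEAD_IDX) & (states != _DEAD_IDX)))

        for i, ind in enumerate(cohort):
            s_new = STATE_ORDER[new_states[i]]
            if s_new is not ind.state:
                ind.state = s_new
                if s_new is State.DEAD:
                    ind.year_of_death = year
            if s_new is not State.DEAD:
                ind.age += 1

        counts = np.bincount(new_states, minlength=len(STATE_ORDER))

        qalys_total = float(u_vec @ counts)
        if discount_qalys:
            qalys_total = discount(qalys_total, t, costs.discount_rate)

        outpatient_ckd = float(
            sum(
                outpatient_vec[STATE_INDEX[s]] * counts[STATE_INDEX[s]]
                for s in (State.CKD_UNDETECTED, State.CKD_DIAGNOSED, State.CKD_TREATED)
            )
        )
        outpatient_esrd = float(outpatient_vec[_ESRD_IDX] * counts[_ESRD_IDX])
        treatment = float(treatment_annual * counts[_TREATED_IDX])

        components = {
            "screening": discount(screening_cost, t, costs.discount_rate),
            "treatment": discount(treatment, t, costs.discount_rate),
            "outpatient_ckd": discount(outpatient_ckd, t, costs.discount_rate),
            "outpatient_esrd": discount(outpatient_esrd, t, costs.discount_rate),
        }

        ledgers.append(
            YearlyLedger(
                year=year,
                state_counts={s: int(counts[STATE_INDEX[s]]) for s in STATE_ORDER},
                new_esrd=new_esrd,
                deaths=deaths,
                qalys_total=qalys_total,
                qalys_per_capita=qalys_total / n0,
                cost_total=sum(components.values()),
                cost_components=components,
            )
        )
    return ledgers


def _seed_scalar(master_seed) -> int:
    """Collapse a (possibly composite) master seed to a scalar for the
    screening participation stream."""
    if isinstance(master_seed, (list, tuple)):
        return int(np.random.SeedSequence(master_seed).generate_state(1)[0] % (2**31))
    return int(master_seed)


def run_paired(
    cohort: Sequence[Individual],
    params: TransitionParameters,
    strategy: Strategy,
    start_year: int,
    horizon: int,
    master_seed,
    utilities: Optional[UtilityParams] = None,
    costs: Optional[CostParams] = None,
    matrices: Optional[tuple[TransitionMatrix, TransitionMatrix]] = None,
    discount_qalys: bool = False,
) -> ScenarioComparison:
    """Run intervention and control arms on the same cohort with common
    random numbers (one shared uniform per individual-year).

    ``matrices``, when given, is the (intervention, control) matrix pair
    overriding those built from ``params``.
    """
    m_int, m_ctl = matrices if matrices is not None else (None, None)
    intervention = run_arm(
        cohort, params, strategy, start_year, horizon, master_seed,
        utilities=utilities, costs=costs, matrix=m_int, discount_qalys=discount_qalys,
    )
    control = run_arm(
        cohort, params, None, start_year, horizon, master_seed,
        utilities=utilities, costs=costs, matrix=m_ctl, discount_qalys=discount_qalys,
    )
    return ScenarioComparison(
        strategy_name=strategy.name, intervention=intervention, control=control
    )


def expected_occupancy(
    initial_counts: Sequence[float],
    matrix: TransitionMatrix,
    horizon: int,
) -> np.ndarray:
    """Deterministic cohort-level expectation of state occupancy.

    Returns an array of shape ``(horizon, n_states)``: the initial count
    vector propagated through the matrix power for years 1..horizon. This
    is the analytic mean the micro-simulation must match.
    """
    if horizon < 1:
        raise ParameterError(f"horizon must be >= 1, got {horizon}")
    v = np.asarray(initial_counts, dtype=float)
    if v.shape != (len(STATE_ORDER),):
        raise ConsistencyError(
            f"initial_counts must have length {len(STATE_ORDER)}, got {v.shape}"
        )
    a = matrix.array  # TransitionMatrix validated row-stochasticity already
    out = np.empty((horizon, len(STATE_ORDER)))
    for t in range(horizon):
        v = v @ a
        out[t] = v
    return out
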