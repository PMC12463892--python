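"""One-way deterministic sensitivity analysis (±10%).

Perturbs one factor group at a time — annual transition probabilities,
unit costs, or health-state utilities — re-runs the paired simulation with
identical seeds (so deltas are not polluted by Monte-Carlo noise), and
reports the induced change in two outputs per arm: the mean annual
discounted economic burden, and the final-year per-capita QALYs.

"Transition probabilities" are perturbed on the derived annual matrix
(off-diagonal event probabilities scaled, diagonal re-normalized), not on
the underlying rates or hazard ratios. Utility perturbation clips at 1
(perfect health is a ceiling), so a cohort containing full-health members
responds asymmetrically to +10% — as real tornado analyses do.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .burden_accounting import CostParams, UtilityParams
from .errors import ConfigurationError, ParameterError
from .screening_strategies import Strategy
from .simulation_engine import ScenarioComparison, run_paired
from .synthetic_population import Individual
from .transition_model import (
    TransitionMatrix,
    TransitionParameters,
    build_transition_matrix,
)

__all__ = [
    "FACTORS",
    "DIRECTIONS",
    "perturb",
    "perturb_matrix",
    "one_way_table",
]

FACTORS = ("transition_probabilities", "costs", "utilities")
DIRECTIONS = {"+10%": 1.10, "-10%": 0.90}

#: Which output each factor speaks to in the one-way table.
_FACTOR_OUTPUTS = {
    "transition_probabilities": ("mean_annual_burden", "final_year_qaly_per_capita"),
    "costs": ("mean_annual_burden",),
    "utilities": ("final_year_qaly_per_capita",),
}


def _direction_factor(direction: Union[str, float]) -> float:
    if isinstance(direction, str):
        if direction not in DIRECTIONS:
            raise ConfigurationError(
                f"direction must be one of {sorted(DIRECTIONS)}, got {direction!r}"
            )
        return DIRECTIONS[direction]
    f = 1.0 + float(direction)
    if f <= 0:
        raise ParameterError(f"perturbation {direction} leaves no positive scale")
    return f


def perturb_matrix(matrix: TransitionMatrix, factor: float) -> TransitionMatrix:
    """Scale every off-diagonal (event) probability by ``factor``.

    Entries are clipped to [0, 1]; if a row's event mass would exceed 1 it
    is renormalized to 1; the diagonal absorbs the remainder. The DEAD row
    has no events and is unchanged.
    """
    a = matrix.array.copy()
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    a[off] = np.clip(a[off] * factor, 0.0, 1.0)
    row_event = a.copy()
    row_event[~off] = 0.0
    sums = row_event.sum(axis=1)
    over = sums > 1.0
    if np.any(over):
        row_event[over] /= sums[over, None]
        a[off] = row_event[off]
        sums = np.minimum(sums, 1.0)
    np.fill_diagonal(a, 1.0 - sums)
    return TransitionMatrix(a)


def perturb(
    obj: Union[CostParams, UtilityParams, TransitionMatrix],
    factor: str,
    direction: Union[str, float],
):
    """Return a copy of ``obj`` with the named factor group scaled ±10%.

    ``factor`` selects the group and must match the object's type:
    ``"costs"`` scales all unit costs of a :class:`CostParams` (the
    discount rate is not a cost and is untouched); ``"utilities"`` scales
    the living-state utilities of a :class:`UtilityParams`, clipped to
    [0, 1]; ``"transition_probabilities"`` scales a
    :class:`TransitionMatrix` via :func:`perturb_matrix`.
    """
    f = _direction_factor(direction)
    if factor == "costs":
        if not isinstance(obj, CostParams):
            raise ConfigurationError("factor 'costs' requires a CostParams")
        return replace(
            obj,
            c_outpatient_ckd=obj.c_outpatient_ckd * f,
            c_outpatient_esrd=obj.c_outpatient_esrd * f,
            c_treatment_weekly=obj.c_treatment_weekly * f,
            c_screen_urinalysis=obj.c_screen_urinalysis * f,
            c_screen_creatinine=obj.c_screen_creatinine * f,
        )
    if factor == "utilities":
        if not isinstance(obj, UtilityParams):
            raise ConfigurationError("factor 'utilities' requires a UtilityParams")
        return replace(
            obj,
            u_at_risk=min(1.0, obj.u_at_risk * f),
            u_ckd=min(1.0, obj.u_ckd * f),
            u_esrd=min(1.0, obj.u_esrd * f),
        )
    if factor == "transition_probabilities":
        if not isinstance(obj, TransitionMatrix):
            raise ConfigurationError(
                "factor 'transition_probabilities' requires a TransitionMatrix"
            )
        return perturb_matrix(obj, f)
    raise ConfigurationError(f"unknown factor {factor!r}; known: {FACTORS}")


def _outputs(comparison: ScenarioComparison) -> dict[tuple[str, str], float]:
    out = {}
    for arm in ("intervention", "control"):
        ledgers = comparison.intervention if arm == "intervention" else comparison.control
        out[("mean_annual_burden", arm)] = sum(l.cost_total for l in ledgers) / len(
            ledgers
        )
        out[("final_year_qaly_per_capita", arm)] = ledgers[-1].qalys_per_capita
    return out


def one_way_table(
    cohort: Sequence[Individual],
    params: TransitionParameters,
    strategy: Strategy,
    horizon: int,
    master_seed,
    start_year: int = 2024,
    utilities: Optional[UtilityParams] = None,
    costs: Optional[CostParams] = None,
    directions: Sequence[str] = ("-10%", "+10%"),
) -> pd.DataFrame:
    """One-way ±10% sensitivity table.

    Re-runs the paired simulation once per (factor, direction) with the
    same master seed as the base case and reports ``delta`` = perturbed
    output − base output, separately per arm. Transition and cost
    perturbations speak to the mean annual burden; transition and utility
    perturbations speak to the final-year per-capita QALYs.

    Returns a tidy DataFrame with columns
    ``factor, direction, arm, output, base, value, delta``.
    """
    utilities = utilities if utilities is not None else UtilityParams()
    costs = costs if costs is not None else CostParams()

    def paired(u, c, matrices=None):
        return run_paired(
            cohort, params, strategy, start_year, horizon, master_seed,
            utilities=u, costs=c, matrices=matrices,
        )

    base = _outputs(paired(utilities, costs))

    rows = []
    for factor in FACTORS:
        for direction in directions:
            f = _direction_factor(direction)
            if factor == "transition_probabilities":
                matrices = (
                    perturb_matrix(build_transition_matrix(params, True), f),
                    perturb_matrix(build_transition_matrix(params, False), f),
                )
                comp = paired(utilities, costs, matrices=matrices)
            elif factor == "costs":
                # Screening unit costs live on the strategy; scale them too
                # so the whole cost group moves together.
                comp = run_paired(
                    cohort, params, strategy.with_costs_scaled(f), start_year,
                    horizon, master_seed,
                    utilities=utilities, costs=perturb(costs, "costs", direction),
                )
            else:
                comp = paired(perturb(utilities, "utilities", direction), costs)
            values = _outputs(comp)
            for output in _FACTOR_OUTPUTS[factor]:
                for arm in ("intervention", "control"):
                    rows.append(
                        {
                            "factor": factor,
                            "direction": direction,
                            "arm": arm,
                            "output": output,
                            "base": base[(output, arm)],
                            "value": values[(output, arm)],
                            "delta": values[(output, arm)] - base[(output, arm)],
                        }
                    )
    return pd.DataFrame(rows)
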