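"""Annual disease-state transition parameters and machinery.

Houses the published transition parameters of the CKD burden model, the
rate-to-probability conversion, hazard-ratio and relative-risk application,
and the construction of the one-year transition matrix over the six-state
space defined in :mod:`ckdsim.states`.

Parameter provenance (all annual):

* general-population all-cause mortality rate 8.87 per mille (city vital
  statistics), converted to a probability via ``1 - exp(-r)``;
* ESRD mortality 3.38%, used directly as an annual probability (it comes
  from a dialysis registry's annual report, already a proportion);
* pre-end-stage CKD mortality hazard ratio 1.63 vs the general population;
* treated-CKD mortality hazard ratio 0.83, read as treated-vs-untreated CKD
  and composed multiplicatively with 1.63;
* ESRD-onset relative risk 0.79 under ACEI/ARB treatment, applied to the
  baseline annual onset probability (default 0.10).

Death competes first within a cycle: onset probabilities apply to the
survivor mass, so matrix entries to ESRD are ``(1 - p_death) * p_onset``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConsistencyError, ParameterError
from .states import SAMPLING_ORDER, STATE_INDEX, STATE_ORDER, State

__all__ = [
    "TransitionParameters",
    "TransitionMatrix",
    "rate_to_probability",
    "apply_hazard_ratio",
    "apply_relative_risk",
    "build_transition_matrix",
]

_ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class TransitionParameters:
    """Annual transition parameters of the CKD state model.

    Attributes
    ----------
    r_gen_mort:
        All-cause mortality *rate* of the general population, per
        person-year (default 8.87 per mille).
    p_esrd_mort:
        Annual death *probability* in ESRD (default 3.38%).
    hr_ckd_mort:
        Hazard ratio of death for pre-end-stage CKD vs the general
        population (default 1.63, published range 1.50-1.77).
    hr_ckd_mort_treated:
        Hazard ratio of death for treated vs untreated pre-end-stage CKD
        (default 0.83, published range 0.78-0.87).
    rr_esrd_treated:
        Relative risk of ESRD onset under ACEI/ARB treatment (default 0.79,
        published range 0.70-0.90).
    p_esrd_base:
        Baseline annual probability of pre-end-stage CKD progressing to
        ESRD (default 0.10).
    p_ckd_incidence:
        Annual probability of AT_RISK -> CKD_UNDETECTED onset; 0 by default
        (closed-cohort mode following patients already identified at entry).
    """

    r_gen_mort: float = 0.00887
    p_esrd_mort: float = 0.0338
    hr_ckd_mort: float = 1.63
    hr_ckd_mort_treated: float = 0.83
    rr_esrd_treated: float = 0.79
    p_esrd_base: float = 0.10
    p_ckd_incidence: float = 0.0

    def __post_init__(self) -> None:
        if self.r_gen_mort < 0:
            raise ParameterError(f"r_gen_mort must be >= 0, got {self.r_gen_mort}")
        for name in ("p_esrd_mort", "p_esrd_base", "p_ckd_incidence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        for name in ("hr_ckd_mort", "hr_ckd_mort_treated", "rr_esrd_treated"):
            v = getattr(self, name)
            if v <= 0:
                raise ParameterError(f"{name} must be > 0, got {v}")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionParameters":
        return cls(**d)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic one-year transition matrix over ``STATE_ORDER``.

    Validated on construction: entries in [0, 1], rows sum to 1 within
    1e-12, DEAD row is the absorbing unit vector.
    """

    array: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.array, dtype=float)
        object.__setattr__(self, "array", a)
        n = len(STATE_ORDER)
        if a.shape != (n, n):
            raise ConsistencyError(f"transition matrix must be {n}x{n}, got {a.shape}")
        if np.any(a < -_ROW_SUM_TOL) or np.any(a > 1 + _ROW_SUM_TOL):
            raise ConsistencyError("transition probabilities outside [0, 1]")
        rowsums = a.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > _ROW_SUM_TOL):
            raise ConsistencyError(f"rows must sum to 1 within {_ROW_SUM_TOL}: {rowsums}")
        dead = STATE_INDEX[State.DEAD]
        unit = np.zeros(n)
        unit[dead] = 1.0
        if not np.array_equal(a[dead], unit):
            raise ConsistencyError("DEAD row must be the absorbing unit vector")

    def __getitem__(self, pair: tuple[State, State]) -> float:
        src, dst = pair
        return float(self.array[STATE_INDEX[src], STATE_INDEX[dst]])

    def row(self, state: State) -> np.ndarray:
        return self.array[STATE_INDEX[state]].copy()

    def sampling_cumulative(self) -> np.ndarray:
        """Per-row cumulative probabilities in ``SAMPLING_ORDER``.

        Used by the engine's inverse-transform draw; worst destinations
        (DEAD, then ESRD) come first so shared uniforms across paired arms
        preserve outcome dominance.
        """
        idx = [STATE_INDEX[s] for s in SAMPLING_ORDER]
        return np.cumsum(self.array[:, idx], axis=1)


def rate_to_probability(r: float) -> float:
    """Convert an annual event rate to an annual event probability.

    Uses the standard constant-rate conversion ``p = 1 - exp(-r)``; the
    result is monotone in ``r``, lies in [0, 1) and never exceeds ``r``.
    """
    if r < 0:
        raise ParameterError(f"rate must be >= 0, got {r}")
    return -math.expm1(-r)


def apply_hazard_ratio(p_base: float, hr: float) -> float:
    """Scale an annual probability on the hazard scale: ``1 - (1-p)**hr``.

    Exactly composes: applying ``a`` then ``b`` equals applying ``a*b``.
    """
    if not 0.0 <= p_base < 1.0:
        raise ParameterError(f"p_base must be in [0, 1), got {p_base}")
    if hr <= 0:
        raise ParameterError(f"hazard ratio must be > 0, got {hr}")
    return -math.expm1(hr * math.log1p(-p_base))


def apply_relative_risk(p: float, rr: float) -> float:
    """Scale an annual probability multiplicatively, clipped at 1."""
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"probability must be in [0, 1], got {p}")
    if rr < 0:
        raise ParameterError(f"relative risk must be >= 0, got {rr}")
    return min(1.0, p * rr)


def build_transition_matrix(
    params: TransitionParameters, treated_variant: bool = True
) -> TransitionMatrix:
    """Build the one-year transition matrix.

    Parameters
    ----------
    params:
        Validated transition parameters.
    treated_variant:
        When True, the CKD_TREATED row carries the intervention effects
        (mortality hazard scaled by ``hr_ckd_mort * hr_ckd_mort_treated``,
        ESRD onset scaled by ``rr_esrd_treated``). When False — the
        no-intervention arm — the CKD_TREATED row is forced equal to the
        CKD_DIAGNOSED row, so treatment status changes accounting only.
    """
    n = len(STATE_ORDER)
    a = np.zeros((n, n))
    i = STATE_INDEX

    def set_row(src: State, entries: dict[State, float]) -> None:
        total = 0.0
        for dst, p in entries.items():
            a[i[src], i[dst]] = p
            total += p
        a[i[src], i[src]] = 1.0 - total

    p_gen = rate_to_probability(params.r_gen_mort)
    p_ckd_death = apply_hazard_ratio(p_gen, params.hr_ckd_mort)

    # AT_RISK: death at the general-population probability; CKD onset on the
    # survivor mass (0 in the default closed-cohort mode).
    set_row(
        State.AT_RISK,
        {
            State.DEAD: p_gen,
            State.CKD_UNDETECTED: (1.0 - p_gen) * params.p_ckd_incidence,
        },
    )

    # Pre-end-stage CKD, untreated (undetected and diagnosed rows identical).
    ckd_row = {
        State.DEAD: p_ckd_death,
        State.ESRD: (1.0 - p_ckd_death) * params.p_esrd_base,
    }
    set_row(State.CKD_UNDETECTED, ckd_row)
    set_row(State.CKD_DIAGNOSED, ckd_row)

    if treated_variant:
        p_treated_death = apply_hazard_ratio(
            p_gen, params.hr_ckd_mort * params.hr_ckd_mort_treated
        )
        p_treated_esrd = apply_relative_risk(params.p_esrd_base, params.rr_esrd_treated)
        set_row(
            State.CKD_TREATED,
            {
                State.DEAD: p_treated_death,
                State.ESRD: (1.0 - p_treated_death) * p_treated_esrd,
            },
        )
    else:
        a[i[State.CKD_TREATED]] = 0.0
        set_row(State.CKD_TREATED, ckd_row)

    set_row(State.ESRD, {State.DEAD: params.p_esrd_mort})
    set_row(State.DEAD, {})

    return TransitionMatrix(a)
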