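"""Disease-state space of the CKD micro-simulation.

The model lumps CKD stages I-IV into three pre-end-stage compartments that
differ only in detection/treatment status; stage V is the end-stage renal
disease (ESRD) compartment. DEAD is absorbing.
"""

from __future__ import annotations

from enum import Enum


class State(str, Enum):
    """One individual's disease state."""

    AT_RISK = "AT_RISK"                  # high-risk, no CKD
    CKD_UNDETECTED = "CKD_UNDETECTED"    # stages I-IV, not yet found
    CKD_DIAGNOSED = "CKD_DIAGNOSED"      # stages I-IV, known but untreated
    CKD_TREATED = "CKD_TREATED"          # stages I-IV, on ACEI/ARB management
    ESRD = "ESRD"                        # stage V / end-stage renal disease
    DEAD = "DEAD"

    def __str__(self) -> str:  # CSV round-trips use the bare token
        return self.value


#: Canonical state ordering used for matrix rows/columns.
STATE_ORDER: tuple[State, ...] = tuple(State)

STATE_INDEX: dict[State, int] = {s: i for i, s in enumerate(STATE_ORDER)}

#: Destination ordering for inverse-transform sampling: worst outcomes first.
#: This ordering is what makes common random numbers across paired arms yield
#: the "intervention never does worse for the same draw" dominance property.
SAMPLING_ORDER: tuple[State, ...] = (
    State.DEAD,
    State.ESRD,
    State.CKD_UNDETECTED,
    State.CKD_DIAGNOSED,
    State.CKD_TREATED,
    State.AT_RISK,
)

#: Pre-end-stage CKD compartments (stages I-IV).
PRE_ESRD_STATES: frozenset[State] = frozenset(
    {State.CKD_UNDETECTED, State.CKD_DIAGNOSED, State.CKD_TREATED}
)

ALIVE_STATES: frozenset[State] = frozenset(s for s in State if s is not State.DEAD)

# Stage-at-entry tokens (reporting only).
STAGE_NONE = "NONE"
STAGE_I_IV = "I-IV"
STAGE_V = "V"
STAGE_TOKENS = (STAGE_NONE, STAGE_I_IV, STAGE_V)
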