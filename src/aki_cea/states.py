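"""Health-state space of the kidney-disease progression model.

The cohort occupies one of four health states (normal kidney function,
chronic kidney disease, end-stage renal disease, death), stratified by
whether the patient experienced an acute kidney injury within 7 days of
catheterization.  Death is absorbing.  The stratification is carried
through the whole horizon because the annual transition probabilities
observed in the trial differ by AKI history.
"""

from __future__ import annotations

from enum import Enum
from typing import NamedTuple


class HealthState(str, Enum):
    NORMAL = "NORMAL"
    CKD = "CKD"
    ESRD = "ESRD"
    DEATH = "DEATH"


class StratifiedState(NamedTuple):
    """A health state tagged with 7-day AKI history."""

    state: HealthState
    aki_history: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        tag = "after_aki" if self.aki_history else "no_aki"
        return f"{self.state.value}[{tag}]"


#: Ordering of the four plain health states used in 30-day disposition rows.
HEALTH_STATES: tuple[HealthState, ...] = (
    HealthState.NORMAL,
    HealthState.CKD,
    HealthState.ESRD,
    HealthState.DEATH,
)

#: Canonical ordering of the stratified state space (AKI-history block first).
#: Death is carried per stratum; total occupancy over all eight entries sums
#: to one.
STATE_SPACE: tuple[StratifiedState, ...] = tuple(
    StratifiedState(s, hist) for hist in (True, False) for s in HEALTH_STATES
)

STATE_INDEX: dict[StratifiedState, int] = {s: i for i, s in enumerate(STATE_SPACE)}

#: Structurally permitted annual transitions (no recovery of kidney function).
PERMITTED_ANNUAL_EXITS: dict[HealthState, tuple[HealthState, ...]] = {
    HealthState.NORMAL: (HealthState.CKD, HealthState.ESRD, HealthState.DEATH),
    HealthState.CKD: (HealthState.ESRD, HealthState.DEATH),
    HealthState.ESRD: (HealthState.DEATH,),
}
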