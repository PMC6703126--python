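"""The 14-state health-state space of the COPD natural-history model.

States partition the cohort into disease-free (with or without respiratory
symptoms), undiagnosed COPD by GOLD stage, diagnosed COPD (untreated or on
inhaled maintenance treatment) by GOLD stage, and dead.  There is no
undiagnosed GOLD 4 state: case-finding studies virtually never surface very
severe disease, so progression out of undiagnosed GOLD 3 presents clinically
and enters the diagnosed tier.
"""

from __future__ import annotations

from enum import IntEnum


class HealthState(IntEnum):
    ASYMPTOMATIC = 0          # no airflow obstruction, no symptoms
    SYMPTOMATIC = 1           # respiratory symptoms, no airflow obstruction
    UNDIAG_GOLD1 = 2
    UNDIAG_GOLD2 = 3
    UNDIAG_GOLD3 = 4
    DIAG_GOLD1 = 5            # diagnosed, not on maintenance treatment
    DIAG_GOLD2 = 6
    DIAG_GOLD3 = 7
    DIAG_GOLD4 = 8
    TREAT_GOLD1 = 9           # diagnosed and on maintenance treatment
    TREAT_GOLD2 = 10
    TREAT_GOLD3 = 11
    TREAT_GOLD4 = 12
    DEAD = 13


N_STATES = len(HealthState)

UNDIAGNOSED = (
    HealthState.UNDIAG_GOLD1,
    HealthState.UNDIAG_GOLD2,
    HealthState.UNDIAG_GOLD3,
)
DIAGNOSED_UNTREATED = (
    HealthState.DIAG_GOLD1,
    HealthState.DIAG_GOLD2,
    HealthState.DIAG_GOLD3,
    HealthState.DIAG_GOLD4,
)
TREATED = (
    HealthState.TREAT_GOLD1,
    HealthState.TREAT_GOLD2,
    HealthState.TREAT_GOLD3,
    HealthState.TREAT_GOLD4,
)
COPD_STATES = UNDIAGNOSED + DIAGNOSED_UNTREATED + TREATED
ALIVE = tuple(s for s in HealthState if s is not HealthState.DEAD)
NON_COPD_ALIVE = (HealthState.ASYMPTOMATIC, HealthState.SYMPTOMATIC)


def gold_stage(state: HealthState) -> int | None:
    """0-based GOLD stage index of a COPD state, None otherwise."""
    if state in UNDIAGNOSED:
        return state - HealthState.UNDIAG_GOLD1
    if state in DIAGNOSED_UNTREATED:
        return state - HealthState.DIAG_GOLD1
    if state in TREATED:
        return state - HealthState.TREAT_GOLD1
    return None


def is_treated(state: HealthState) -> bool:
    return state in TREATED


def is_diagnosed(state: HealthState) -> bool:
    return state in DIAGNOSED_UNTREATED or state in TREATED
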