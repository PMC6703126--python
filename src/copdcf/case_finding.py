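"""Systematic case-finding overlay: the questionnaire/spirometry cascade.

Every `interval_years` (default 3) the whole surviving cohort is mailed a
respiratory symptom screening questionnaire.  Responders who report symptoms
are invited for confirmatory spirometry.  Undiagnosed COPD patients who
complete the cascade become diagnosed; symptomatic patients without airflow
obstruction complete spirometry (and incur its cost) but receive no
diagnosis.  Routine-care diagnosis, common to both strategies, is handled in
the cohort engine.

Symptom reporting is conditioned on the health state: the state space already
separates symptomatic from asymptomatic members, so the probability of
reporting symptoms *given symptomatic* defaults to 1 rather than re-applying
a trial-level aggregate reporting rate (which would double-count the symptom
information carried by the state).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .states import ALIVE, HealthState, UNDIAGNOSED

__all__ = [
    "StrategyConfig",
    "is_screening_cycle",
    "casefinding_diagnosis_prob",
    "casefinding_cycle_cost",
    "routine_care",
]


@dataclass
class StrategyConfig:
    """One arm of the evaluation: case-finding on/off plus cascade inputs.

    Probabilities are per screening round; costs are GBP per contact.
    """

    enabled: bool = True
    interval_years: float = 3.0
    p_receive: float = 0.999          # questionnaire reaches the patient
    p_respond: float = 0.355          # questionnaire returned
    p_report_symptomatic: float = 1.0  # symptoms reported given symptomatic
    p_attend: float = 0.661           # attends confirmatory spirometry
    cost_questionnaire: float = 4.01
    cost_spirometry: float = 55.27

    def validate(self, cycle_years: float = 0.25) -> None:
        for name in ("p_receive", "p_respond", "p_report_symptomatic", "p_attend"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"case_finding.{name}={v} must be in [0, 1]")
        for name in ("cost_questionnaire", "cost_spirometry"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"case_finding.{name}={v} must be >= 0")
        if self.interval_years <= 0:
            raise ValueError("case_finding.interval_years must be positive")
        n = self.interval_years / cycle_years
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"case_finding.interval_years={self.interval_years} must be a "
                f"positive multiple of the cycle length ({cycle_years}y)"
            )

    @property
    def cascade_probability(self) -> float:
        """Probability an undiagnosed (symptomatic) patient completes the
        cascade through spirometry in one screening round."""
        return (
            self.p_receive
            * self.p_respond
            * self.p_report_symptomatic
            * self.p_attend
        )


def routine_care(config: StrategyConfig) -> StrategyConfig:
    """The comparator: same cascade parameters, case-finding switched off."""
    return replace(config, enabled=False)


def is_screening_cycle(
    cycle: int, config: StrategyConfig, cycle_years: float = 0.25
) -> bool:
    """True iff `cycle` starts a screening round (cycle 0 is a round)."""
    if not config.enabled:
        return False
    per_round = round(config.interval_years / cycle_years)
    return cycle % per_round == 0


def casefinding_diagnosis_prob(state: HealthState, config: StrategyConfig) -> float:
    """Per-round probability that case-finding diagnoses a member of `state`.

    Spirometry is treated as a perfect test of true airflow obstruction, so
    only undiagnosed COPD states can be diagnosed; disease-free and already
    diagnosed states return 0.
    """
    if state in UNDIAGNOSED:
        return config.cascade_probability
    return 0.0


def casefinding_cycle_cost(
    occupancy: np.ndarray,
    config: StrategyConfig,
    cycle: int | None = None,
    cycle_years: float = 0.25,
) -> float:
    """Case-finding cost (GBP per cohort member) charged in a screening cycle.

    The questionnaire is mailed to every flagged (alive) member; spirometry
    costs fall on the mass that reaches the test: symptomatic members, with
    or without airflow obstruction.  Pass `cycle` to have non-screening
    cycles priced at zero.
    """
    if cycle is not None and not is_screening_cycle(cycle, config, cycle_years):
        return 0.0
    occupancy = np.asarray(occupancy, dtype=float)
    alive = float(occupancy[list(ALIVE)].sum())
    quest = config.p_receive * config.cost_questionnaire * alive
    symptomatic_mass = float(
        occupancy[[HealthState.SYMPTOMATIC, *UNDIAGNOSED]].sum()
    )
    spiro = config.cascade_probability * symptomatic_mass * config.cost_spirometry
    return quest + spiro
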