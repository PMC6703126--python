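"""Markov cohort engine: evolve state occupancy over 3-month cycles.

Each cycle a 14x14 row-stochastic transition matrix is assembled from the
parameter set, the cohort's current age, and the strategy (case-finding on
or off).  Structural rules enforced by construction:

* disease can only worsen one GOLD stage per cycle (no skip deterioration);
* diagnosed patients never revert to undiagnosed, treated never to untreated;
* stage improvement occurs only in treated states (the annual GOLD matrix's
  improvement entries are dropped — mass stays put — in undiagnosed and
  untreated states);
* there is no undiagnosed GOLD 4 state: progression out of undiagnosed
  GOLD 3 presents clinically and enters diagnosed-untreated GOLD 4;
* dead is absorbing.

Annual probabilities become quarterly via per-entry competing-risks rate
conversion: a row with off-diagonal annual mass ``S`` has total quarterly
exit ``1 - (1 - S)**cycle_years`` shared among destinations in proportion
to their annual probabilities.  This avoids the embedding problem of a
matrix fourth root.  Treatment effects (odds ratios on progression,
mortality and exacerbation) apply on the annual scale before conversion.
Within a cycle: newly diagnosed patients cannot also initiate treatment,
and patients keep their start-of-cycle dynamics until the cycle ends, so
the composed matrix contains no improvement mass in undiagnosed or
untreated rows.  Severe exacerbations are within-state events whose case
fatality competes multiplicatively with the other death causes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .case_finding import (
    StrategyConfig,
    casefinding_cycle_cost,
    casefinding_diagnosis_prob,
    is_screening_cycle,
)
from .economics import (
    Trace,
    discount_factor,
    state_cost_vector,
    state_utility_vector,
    exacerbation_decrement_vector,
)
from .parameters import ParameterSet, annual_to_cycle_prob, apply_odds_ratio
from .states import (
    COPD_STATES,
    DIAGNOSED_UNTREATED,
    HealthState,
    N_STATES,
    TREATED,
    UNDIAGNOSED,
    gold_stage,
    is_treated,
)
from .synthetic_inputs import AgeProfile, LifeTable, default_model_inputs

logger = logging.getLogger(__name__)

__all__ = [
    "CohortState",
    "background_mortality",
    "build_cycle_matrix",
    "cycle_exacerbation_probs",
    "step_cycle",
    "run_cohort",
    "check_matrix",
    "starting_occupancy",
]

_MASS_TOL = 1e-10


@dataclass
class CohortState:
    """Occupancy vector plus clock, with the exacerbation event mass of the
    most recent cycle pending accrual."""

    occupancy: np.ndarray
    age: float
    cycle: int = 0
    exac_mass: np.ndarray = field(default_factory=lambda: np.zeros(N_STATES))

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.shape != (N_STATES,):
            raise ValueError(f"occupancy must have {N_STATES} entries")
        if np.any(self.occupancy < -_MASS_TOL):
            raise ValueError("occupancy fractions must be >= 0")
        if abs(self.occupancy.sum() - 1.0) > 1e-8:
            raise ValueError(
                f"occupancy must sum to 1, got {self.occupancy.sum():.12f}"
            )


def starting_occupancy(ps: ParameterSet) -> np.ndarray:
    """Initial distribution: disease-free with/without symptoms plus prevalent
    undiagnosed COPD split over GOLD 1-3."""
    occ = np.zeros(N_STATES)
    occ[HealthState.ASYMPTOMATIC] = ps.cohort.frac_asymptomatic
    occ[HealthState.SYMPTOMATIC] = ps.cohort.frac_symptomatic
    split = np.asarray(ps.cohort.gold_split, dtype=float)
    split = split / split.sum()
    for g, s in enumerate(UNDIAGNOSED):
        occ[s] = ps.cohort.frac_undiagnosed * split[g]
    return occ / occ.sum()


def background_mortality(
    age: float,
    sex_mix: float,
    life_table: LifeTable,
    cycle_years: float = 0.25,
) -> float:
    """Per-cycle all-cause death probability for non-COPD states: the
    sex-blended annual probability from the (COPD-adjusted) life table,
    rate-converted to the cycle length.  COPD states instead carry the
    disease-specific all-cause death column of the annual GOLD matrix."""
    return annual_to_cycle_prob(life_table.annual_probability(age, sex_mix), cycle_years)


def _quarterly_split(annual: np.ndarray, cycle_years: float) -> np.ndarray:
    """Per-entry competing-risks conversion of an annual off-diagonal row."""
    total = float(annual.sum())
    if total <= 0.0:
        return np.zeros_like(annual)
    if total >= 1.0:
        logger.warning("annual off-diagonal mass %.4f >= 1; renormalised", total)
        annual = annual / total
        total = 1.0 - 1e-12
    q_total = 1.0 - (1.0 - total) ** cycle_years
    return annual * (q_total / total)


def _gold_dynamics(
    ps: ParameterSet, g: int, treated: bool, m_prog: float, m_mort: float
) -> tuple[float, float, float, float]:
    """Per-cycle (stay, progress, improve, death) for a GOLD-stage `g`
    (0-based) state, exacerbation fatality folded into death."""
    nh = ps.natural_history
    gm = np.asarray(nh.gold_matrix, dtype=float)
    cy = ps.analysis.cycle_years
    prog_a = min(gm[g, g + 1] * m_prog, 1.0) if g < 3 else 0.0
    impr_a = gm[g, g - 1] if (treated and g > 0) else 0.0
    death_a = min(gm[g, 4] * m_mort, 1.0)
    if treated:
        tr = ps.treatment
        if prog_a > 0:
            prog_a = apply_odds_ratio(prog_a, tr.or_progression)
        death_a = apply_odds_ratio(death_a, tr.or_mortality)
    q = _quarterly_split(np.array([prog_a, impr_a, death_a]), cy)
    prog_q, impr_q, death_q = q
    # severe exacerbation: within-state event with case fatality as a
    # competing death cause, applied multiplicatively on survival
    exac_a = float(nh.p_exacerbation[g])
    if treated:
        exac_a = apply_odds_ratio(exac_a, ps.treatment.or_exacerbation)
    exac_q = annual_to_cycle_prob(exac_a, cy)
    p_exd = exac_q * nh.p_exacerbation_fatality
    prog_q *= 1.0 - p_exd
    impr_q *= 1.0 - p_exd
    death_total = 1.0 - (1.0 - death_q) * (1.0 - p_exd)
    stay = 1.0 - prog_q - impr_q - death_total
    return stay, prog_q, impr_q, death_total


def cycle_exacerbation_probs(ps: ParameterSet) -> np.ndarray:
    """Per-cycle severe-exacerbation probability per state (0 outside COPD
    states; treated states odds-adjusted on the annual scale)."""
    cy = ps.analysis.cycle_years
    out = np.zeros(N_STATES)
    for s in COPD_STATES:
        g = gold_stage(s)
        p_a = float(ps.natural_history.p_exacerbation[g])
        if is_treated(s):
            p_a = apply_odds_ratio(p_a, ps.treatment.or_exacerbation)
        out[s] = annual_to_cycle_prob(p_a, cy)
    return out


def build_cycle_matrix(
    ps: ParameterSet,
    age: float,
    strategy: StrategyConfig,
    cycle: int,
    life_table: LifeTable,
    profiles: AgeProfile,
) -> np.ndarray:
    """Assemble the 14x14 per-cycle transition matrix for one cycle.

    Age enters through the life table (integer age) and the log-linear age
    profiles for incidence, progression and COPD-state mortality.
    """
    cy = ps.analysis.cycle_years
    age_i = float(int(age))  # life table and profiles resolve integer ages
    m_prog = profiles.multiplier("progression", age_i)
    m_mort = profiles.multiplier("copd_mortality", age_i)
    m_inc = profiles.multiplier("incidence", age_i)
    screening = is_screening_cycle(cycle, strategy, cy)

    M = np.zeros((N_STATES, N_STATES))
    nh = ps.natural_history

    # --- disease-free states -------------------------------------------------
    p_bg_a = life_table.annual_probability(age_i, ps.cohort.male_fraction)
    q = _quarterly_split(np.array([nh.p_symptom_onset, p_bg_a]), cy)
    M[HealthState.ASYMPTOMATIC, HealthState.SYMPTOMATIC] = q[0]
    M[HealthState.ASYMPTOMATIC, HealthState.DEAD] = q[1]
    M[HealthState.ASYMPTOMATIC, HealthState.ASYMPTOMATIC] = 1.0 - q.sum()

    inc_a = min(nh.p_copd_incidence * m_inc, 1.0)
    s1 = nh.incident_gold1_fraction
    q = _quarterly_split(np.array([inc_a * s1, inc_a * (1.0 - s1), p_bg_a]), cy)
    M[HealthState.SYMPTOMATIC, HealthState.UNDIAG_GOLD1] = q[0]
    M[HealthState.SYMPTOMATIC, HealthState.UNDIAG_GOLD2] = q[1]
    M[HealthState.SYMPTOMATIC, HealthState.DEAD] = q[2]
    M[HealthState.SYMPTOMATIC, HealthState.SYMPTOMATIC] = 1.0 - q.sum()

    # --- undiagnosed COPD ----------------------------------------------------
    p_routine_q = annual_to_cycle_prob(ps.care.p_routine_diagnosis, cy)
    for s in UNDIAGNOSED:
        g = gold_stage(s)
        stay, prog, _, death = _gold_dynamics(ps, g, False, m_prog, m_mort)
        p_cf = casefinding_diagnosis_prob(s, strategy) if screening else 0.0
        p_dx = 1.0 - (1.0 - p_routine_q) * (1.0 - p_cf)
        M[s, DIAGNOSED_UNTREATED[g]] = p_dx * stay
        M[s, s] = (1.0 - p_dx) * stay
        if g < 2:
            M[s, DIAGNOSED_UNTREATED[g + 1]] = p_dx * prog
            M[s, UNDIAGNOSED[g + 1]] = (1.0 - p_dx) * prog
        else:
            # undiagnosed GOLD 3 deterioration presents clinically
            M[s, HealthState.DIAG_GOLD4] = prog
        M[s, HealthState.DEAD] = death

    # --- diagnosed, untreated ------------------------------------------------
    p_tx_q = annual_to_cycle_prob(ps.care.p_treatment_initiation, cy)
    for s in DIAGNOSED_UNTREATED:
        g = gold_stage(s)
        stay, prog, _, death = _gold_dynamics(ps, g, False, m_prog, m_mort)
        M[s, TREATED[g]] = p_tx_q * stay
        M[s, s] = (1.0 - p_tx_q) * stay
        if g < 3:
            M[s, TREATED[g + 1]] += p_tx_q * prog
            M[s, DIAGNOSED_UNTREATED[g + 1]] += (1.0 - p_tx_q) * prog
        M[s, HealthState.DEAD] = death

    # --- diagnosed, treated --------------------------------------------------
    for s in TREATED:
        g = gold_stage(s)
        stay, prog, impr, death = _gold_dynamics(ps, g, True, m_prog, m_mort)
        M[s, s] = stay
        if g < 3:
            M[s, TREATED[g + 1]] = prog
        if g > 0:
            M[s, TREATED[g - 1]] = impr
        M[s, HealthState.DEAD] = death

    M[HealthState.DEAD, HealthState.DEAD] = 1.0
    return M


def check_matrix(M: np.ndarray, tol: float = _MASS_TOL) -> None:
    """Raise if `M` violates row-stochasticity or a structural zero."""
    if M.shape != (N_STATES, N_STATES):
        raise ValueError("transition matrix must be 14x14")
    if np.any(M < -tol):
        raise ValueError("transition matrix has negative entries")
    rows = M.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > 1e-9):
        raise ValueError(f"transition matrix rows must sum to 1, got {rows}")
    dead_row = np.zeros(N_STATES)
    dead_row[HealthState.DEAD] = 1.0
    if not np.array_equal(M[HealthState.DEAD], dead_row):
        raise ValueError("dead must be absorbing")
    # no skip deterioration, no un-diagnosis, no untreated/undiagnosed improvement
    for tier in (UNDIAGNOSED, DIAGNOSED_UNTREATED, TREATED):
        for s in tier:
            g = gold_stage(s)
            for dest in COPD_STATES:
                gd = gold_stage(dest)
                if gd > g + 1 and M[s, dest] > tol:
                    raise ValueError(f"skip deterioration {s.name} -> {dest.name}")
                if gd < g and M[s, dest] > tol and not is_treated(s):
                    raise ValueError(f"improvement in untreated {s.name} -> {dest.name}")
    for s in DIAGNOSED_UNTREATED + TREATED:
        if M[s, list(UNDIAGNOSED)].sum() > tol or M[
            s, [HealthState.ASYMPTOMATIC, HealthState.SYMPTOMATIC]
        ].sum() > tol:
            raise ValueError(f"diagnosis cannot be reversed from {s.name}")
    for s in TREATED:
        if M[s, list(DIAGNOSED_UNTREATED)].sum() > tol:
            raise ValueError(f"treated state {s.name} cannot revert to untreated")


def step_cycle(
    state: CohortState, matrix: np.ndarray, ps: ParameterSet
) -> CohortState:
    """Advance the cohort one cycle: record the severe-exacerbation event
    mass of the cycle, apply the transition matrix, advance age."""
    occ = state.occupancy
    exac_mass = occ * cycle_exacerbation_probs(ps)
    new_occ = occ @ matrix
    if abs(new_occ.sum() - occ.sum()) > 1e-9:
        raise RuntimeError(
            f"mass not conserved in cycle {state.cycle}: "
            f"{occ.sum():.12f} -> {new_occ.sum():.12f}"
        )
    return CohortState(
        occupancy=new_occ,
        age=state.age + ps.analysis.cycle_years,
        cycle=state.cycle + 1,
        exac_mass=exac_mass,
    )


def run_cohort(
    ps: ParameterSet,
    strategy: StrategyConfig | None = None,
    life_table: LifeTable | None = None,
    profiles: AgeProfile | None = None,
) -> Trace:
    """Deterministic cohort run over the full time horizon (default 50 years
    = 200 quarterly cycles), returning the per-cycle :class:`Trace`.

    Accrual uses start-of-cycle occupancy; case-finding costs are charged at
    the start of each screening round.
    """
    if strategy is None:
        strategy = ps.case_finding
    if life_table is None or profiles is None:
        lt, pr = default_model_inputs(ps)
        life_table = life_table if life_table is not None else lt
        profiles = profiles if profiles is not None else pr
    strategy.validate(ps.analysis.cycle_years)

    cy = ps.analysis.cycle_years
    n_cycles = round(ps.analysis.horizon_years / cy)
    if n_cycles <= 0:
        raise ValueError("time horizon must cover at least one cycle")
    age0 = ps.cohort.start_age

    # static per-state vectors (age profiles do not touch them)
    u_vec = state_utility_vector(ps)
    c_vec = state_cost_vector(ps)
    d_vec = exacerbation_decrement_vector(ps)
    exac_q = cycle_exacerbation_probs(ps)
    exac_cost = ps.costs.exacerbation_episode

    occupancy = np.zeros((n_cycles + 1, N_STATES))
    occupancy[0] = starting_occupancy(ps)
    ages = age0 + cy * np.arange(n_cycles + 1)
    exac_mass = np.zeros((n_cycles, N_STATES))
    cost = np.zeros(n_cycles)
    qaly = np.zeros(n_cycles)
    screening_cost = np.zeros(n_cycles)

    cache: dict[tuple[int, bool], np.ndarray] = {}
    for k in range(n_cycles):
        age = ages[k]
        screening = is_screening_cycle(k, strategy, cy)
        key = (int(age), screening)
        M = cache.get(key)
        if M is None:
            M = build_cycle_matrix(ps, age, strategy, k, life_table, profiles)
            cache[key] = M
        occ = occupancy[k]
        exac_mass[k] = occ * exac_q
        if screening:
            screening_cost[k] = casefinding_cycle_cost(occ, strategy)
        qaly[k] = occ @ u_vec * cy - exac_mass[k] @ d_vec
        cost[k] = occ @ c_vec + exac_mass[k].sum() * exac_cost + screening_cost[k]
        occupancy[k + 1] = occ @ M
        s = occupancy[k + 1].sum()
        if abs(s - 1.0) > 1e-9:
            raise RuntimeError(f"mass not conserved at cycle {k}: sum={s:.12f}")

    return Trace(
        ages=ages,
        occupancy=occupancy,
        exac_mass=exac_mass,
        cost=cost,
        qaly=qaly,
        screening_cost=screening_cost,
        discount=np.asarray(
            discount_factor(np.arange(n_cycles), ps.analysis.discount_rate, cy)
        ),
        cycle_years=cy,
        discount_rate=ps.analysis.discount_rate,
    )
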