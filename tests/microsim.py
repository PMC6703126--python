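"""Individual-level Monte-Carlo oracle for the cohort engine.

Simulates `n` patients through the same per-cycle transition matrices and
event probabilities as the cohort model, but by sampling each individual's
path and accruing discounted costs and QALYs per person.  The cohort
model's totals are expectations of this process, so its discounted means
must agree with the simulated means within Monte-Carlo error — an
independent check of the occupancy algebra, accrual bookkeeping and
discounting.

Event draws (transition, exacerbation, questionnaire receipt, spirometry
attendance) are sampled independently of one another; the exacerbation case
fatality is already folded into the transition matrix.  Independence leaves
all expectations — and therefore the comparison of means — unchanged.
"""

from __future__ import annotations

import numpy as np

import copdcf as cf
from copdcf.case_finding import is_screening_cycle
from copdcf.cohort_engine import (
    build_cycle_matrix,
    cycle_exacerbation_probs,
    starting_occupancy,
)
from copdcf.economics import (
    exacerbation_decrement_vector,
    state_cost_vector,
    state_utility_vector,
)
from copdcf.states import N_STATES, HealthState, UNDIAGNOSED


def simulate_individuals(ps, strategy, life_table, profiles, n, seed):
    """Returns dict with per-person discounted cost and QALY arrays plus
    their means and Monte-Carlo standard errors."""
    rng = np.random.default_rng(seed)
    cy = ps.analysis.cycle_years
    n_cycles = round(ps.analysis.horizon_years / cy)
    rate = ps.analysis.discount_rate

    u = state_utility_vector(ps)
    c = state_cost_vector(ps)
    d = exacerbation_decrement_vector(ps)
    exq = cycle_exacerbation_probs(ps)
    cfg = strategy
    cascade = cfg.cascade_probability

    start = starting_occupancy(ps)
    states = rng.choice(N_STATES, size=n, p=start)
    cost = np.zeros(n)
    qaly = np.zeros(n)

    spiro_eligible = np.zeros(N_STATES, dtype=bool)
    spiro_eligible[HealthState.SYMPTOMATIC] = True
    for s in UNDIAGNOSED:
        spiro_eligible[s] = True

    cache: dict[tuple[int, bool], np.ndarray] = {}
    for k in range(n_cycles):
        age = ps.cohort.start_age + k * cy
        screening = is_screening_cycle(k, cfg, cy)
        key = (int(age), screening)
        cum = cache.get(key)
        if cum is None:
            M = build_cycle_matrix(ps, age, cfg, k, life_table, profiles)
            cum = np.cumsum(M, axis=1)
            cache[key] = cum
        df = (1.0 + rate) ** (-k * cy)
        alive = states != HealthState.DEAD

        qaly += df * u[states] * cy
        cost += df * c[states]

        hit = rng.random(n) < exq[states]
        cost[hit] += df * ps.costs.exacerbation_episode
        qaly[hit] -= df * d[states[hit]]

        if screening:
            mailed = alive & (rng.random(n) < cfg.p_receive)
            cost[mailed] += df * cfg.cost_questionnaire
            attends = spiro_eligible[states] & (rng.random(n) < cascade)
            cost[attends] += df * cfg.cost_spirometry

        r = rng.random(n)
        states = (cum[states] < r[:, None]).sum(axis=1)

    return {
        "cost": cost,
        "qaly": qaly,
        "mean_cost": float(cost.mean()),
        "mean_qaly": float(qaly.mean()),
        "se_cost": float(cost.std(ddof=1) / np.sqrt(n)),
        "se_qaly": float(qaly.std(ddof=1) / np.sqrt(n)),
    }
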