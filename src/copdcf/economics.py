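"""Cost and QALY accrual, discounting, and the cost-effectiveness analyses.

The cohort engine produces a :class:`Trace` per strategy — per-cycle state
occupancy with cost and QALY accruals, discounted and undiscounted.  This
module defines the accrual rules (state utilities and costs, treatment
utility gain, exacerbation disutility and episode costs, case-finding
costs) and the downstream analyses: the incremental cost-effectiveness
ratio (ICER), probabilistic sensitivity analysis (PSA), cost-effectiveness
acceptability curves (CEAC), one-way sensitivity analysis and threshold
search.

Accrual conventions: rewards accrue on the occupancy at the start of each
3-month cycle with no half-cycle correction; annual costs are spread evenly
across the four cycles; a severe exacerbation charges the inpatient episode
cost and a utility decrement of 50% of the stage disutility for one month
plus 25% for two further months (|d|/12 QALYs), all in the event cycle.
Discounting applies factor ``(1 + rate)**(-cycle * cycle_years)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .parameters import ParameterSet, sample_parameter_set, set_by_path
from .case_finding import StrategyConfig, routine_care
from .states import (
    DIAGNOSED_UNTREATED,
    HealthState,
    N_STATES,
    TREATED,
    UNDIAGNOSED,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Trace",
    "CEPair",
    "CEACCurve",
    "ICERResult",
    "discount_factor",
    "state_utility_vector",
    "state_cost_vector",
    "exacerbation_decrement_vector",
    "cycle_accrual",
    "icer",
    "run_psa",
    "ceac",
    "one_way_sensitivity",
    "threshold_search",
    "DEFAULT_WTP_GRID",
]

DEFAULT_WTP_GRID = np.arange(0.0, 50_500.0, 500.0)


# ---------------------------------------------------------------------------
# Accrual primitives
# ---------------------------------------------------------------------------

def discount_factor(cycle, rate: float, cycle_years: float):
    """Discount factor ``(1 + rate)**(-cycle * cycle_years)`` (cycle 0 -> 1)."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + rate) ** (-np.asarray(cycle, dtype=float) * cycle_years)


def state_utility_vector(ps: ParameterSet) -> np.ndarray:
    """Utility weight per health state.  COPD states share the GOLD-stage
    utilities regardless of diagnosis; treated states add the treatment
    utility gain (capped at full health); dead is 0."""
    u = np.zeros(N_STATES)
    u[HealthState.ASYMPTOMATIC] = ps.utilities.asymptomatic
    u[HealthState.SYMPTOMATIC] = ps.utilities.symptomatic
    gold = np.asarray(ps.utilities.gold, dtype=float)
    for g, s in enumerate(UNDIAGNOSED):
        u[s] = gold[g]
    for g, s in enumerate(DIAGNOSED_UNTREATED):
        u[s] = gold[g]
    for g, s in enumerate(TREATED):
        u[s] = min(gold[g] + ps.treatment.utility_gain, 1.0)
    return u


def state_cost_vector(ps: ParameterSet) -> np.ndarray:
    """Routine-management cost per state per cycle (GBP).  Only diagnosed
    states accrue scheduled care and only treated states accrue maintenance
    medication; undiagnosed and disease-free states cost nothing outside
    exacerbation episodes and case-finding contacts."""
    cy = ps.analysis.cycle_years
    c = np.zeros(N_STATES)
    sched = np.asarray(ps.costs.scheduled_care, dtype=float)
    med = np.asarray(ps.costs.medication, dtype=float)
    for g, s in enumerate(DIAGNOSED_UNTREATED):
        c[s] = sched[g] * cy
    for g, s in enumerate(TREATED):
        c[s] = (sched[g] + med[g]) * cy
    return c


def exacerbation_decrement_vector(ps: ParameterSet) -> np.ndarray:
    """QALY loss per severe exacerbation event, by state of the exacerbating
    patient: (0.50 + 0.25 + 0.25) disutility-months = |d_stage| / 12 years,
    scaled by the configurable duration multiplier."""
    d = np.zeros(N_STATES)
    mags = np.abs(np.asarray(ps.utilities.exacerbation_disutility, dtype=float))
    factor = ps.utilities.exacerbation_duration_multiplier * (0.50 + 0.25 + 0.25) / 12.0
    for states in (UNDIAGNOSED, DIAGNOSED_UNTREATED, TREATED):
        for g, s in enumerate(states):
            d[s] = mags[g] * factor
    return d


def cycle_accrual(
    occupancy: np.ndarray,
    exac_mass: np.ndarray,
    ps: ParameterSet,
    screening_costs: float = 0.0,
) -> tuple[float, float]:
    """Undiscounted (cost GBP, QALY years) accrued in one cycle.

    ``occupancy`` is the start-of-cycle state distribution; ``exac_mass`` the
    per-state fraction experiencing a severe exacerbation this cycle.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    exac_mass = np.asarray(exac_mass, dtype=float)
    u = state_utility_vector(ps)
    c = state_cost_vector(ps)
    qaly = float(occupancy @ u) * ps.analysis.cycle_years
    qaly -= float(exac_mass @ exacerbation_decrement_vector(ps))
    cost = float(occupancy @ c)
    cost += float(exac_mass.sum()) * ps.costs.exacerbation_episode
    cost += screening_costs
    return cost, qaly


# ---------------------------------------------------------------------------
# Trace
# ---------------------------------------------------------------------------

@dataclass
class Trace:
    """Per-cycle record of one strategy run.

    occupancy has ``n_cycles + 1`` rows (initial distribution included);
    accrual arrays have ``n_cycles`` entries, one per cycle lived.
    """

    ages: np.ndarray                 # age at the start of each cycle (+ final)
    occupancy: np.ndarray            # (n_cycles + 1, 14)
    exac_mass: np.ndarray            # (n_cycles, 14)
    cost: np.ndarray                 # undiscounted GBP per cycle
    qaly: np.ndarray                 # undiscounted QALYs per cycle
    screening_cost: np.ndarray       # case-finding component of `cost`
    discount: np.ndarray             # discount factor per cycle
    cycle_years: float
    discount_rate: float

    @property
    def n_cycles(self) -> int:
        return len(self.cost)

    @property
    def total_cost(self) -> float:
        """Discounted lifetime cost per cohort member (GBP)."""
        # elementwise product, then the same summation order as the
        # undiscounted total, so a zero rate reproduces it exactly
        return float((self.cost * self.discount).sum())

    @property
    def total_qaly(self) -> float:
        """Discounted lifetime QALYs per cohort member."""
        return float((self.qaly * self.discount).sum())

    @property
    def total_cost_undiscounted(self) -> float:
        return float(self.cost.sum())

    @property
    def total_qaly_undiscounted(self) -> float:
        return float(self.qaly.sum())

    def to_frame(self) -> pd.DataFrame:
        n = self.n_cycles
        data = {"cycle": np.arange(n), "age": self.ages[:n]}
        for s in HealthState:
            data[s.name.lower()] = self.occupancy[:n, s]
        data["exacerbation_mass"] = self.exac_mass.sum(axis=1)
        data["cost"] = self.cost
        data["qaly"] = self.qaly
        data["screening_cost"] = self.screening_cost
        data["discount"] = self.discount
        data["cost_discounted"] = self.cost * self.discount
        data["qaly_discounted"] = self.qaly * self.discount
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ICER
# ---------------------------------------------------------------------------

class CEPair(NamedTuple):
    """Incremental cost (GBP) and incremental QALYs for one PSA draw."""

    delta_cost: float
    delta_qaly: float


@dataclass
class ICERResult:
    delta_cost: float
    delta_qaly: float
    value: float          # GBP/QALY; NaN when undefined
    label: str            # "icer" | "dominant" | "dominated" | "undefined"

    def __str__(self) -> str:
        if self.label == "icer":
            return f"{self.value:.2f} GBP/QALY"
        return self.label


def _totals(x) -> tuple[float, float]:
    if isinstance(x, Trace):
        return x.total_cost, x.total_qaly
    cost, qaly = x
    return float(cost), float(qaly)


def icer(intervention, comparator) -> ICERResult:
    """Incremental cost-effectiveness ratio of `intervention` over
    `comparator` (each a :class:`Trace` or a ``(cost, qaly)`` pair).

    Returns the ratio when incremental QALYs are positive, the label
    ``dominant`` when the intervention is cheaper and more effective,
    ``dominated`` when it is costlier and less effective, and ``undefined``
    when incremental QALYs are zero.
    """
    ci, qi = _totals(intervention)
    cc, qc = _totals(comparator)
    dc, dq = ci - cc, qi - qc
    if dq > 0:
        label = "dominant" if dc < 0 else "icer"
        return ICERResult(dc, dq, dc / dq, label)
    if dq < 0:
        label = "dominated" if dc > 0 else "icer"
        return ICERResult(dc, dq, dc / dq, label)
    label = "undefined" if dc != 0 else "equivalent"
    return ICERResult(dc, dq, float("nan"), label)


# ---------------------------------------------------------------------------
# Strategy pair evaluation
# ---------------------------------------------------------------------------

def _evaluate_strategies(
    ps: ParameterSet,
    life_table,
    profiles,
    strategies: Sequence[StrategyConfig] | None = None,
) -> tuple[Trace, Trace]:
    from .cohort_engine import run_cohort

    if strategies is None:
        strategies = (ps.case_finding, routine_care(ps.case_finding))
    intervention, comparator = strategies
    return (
        run_cohort(ps, intervention, life_table, profiles),
        run_cohort(ps, comparator, life_table, profiles),
    )


def _default_inputs(ps: ParameterSet, life_table, profiles):
    from .synthetic_inputs import default_model_inputs

    if life_table is None or profiles is None:
        lt, pr = default_model_inputs(ps)
        life_table = life_table if life_table is not None else lt
        profiles = profiles if profiles is not None else pr
    return life_table, profiles


# ---------------------------------------------------------------------------
# PSA / CEAC
# ---------------------------------------------------------------------------

def run_psa(
    base: ParameterSet,
    n: int,
    seed: int,
    strategies: Sequence[StrategyConfig] | None = None,
    life_table=None,
    profiles=None,
) -> list[CEPair]:
    """Second-order Monte Carlo: `n` parameter sets drawn from their
    uncertainty distributions, each run through both strategies.

    The life table and age profiles are held fixed across draws (the
    starting-cohort composition and all tabulated inputs are resampled).
    Reproducible given `seed`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    life_table, profiles = _default_inputs(base, life_table, profiles)
    rng = np.random.default_rng(seed)
    pairs: list[CEPair] = []
    for i in range(n):
        ps = sample_parameter_set(base, rng)
        strats = strategies
        if strats is None:
            # cascade parameters are sampled too: both arms share them
            strats = (ps.case_finding, routine_care(ps.case_finding))
        ti, tc = _evaluate_strategies(ps, life_table, profiles, strats)
        pairs.append(CEPair(ti.total_cost - tc.total_cost, ti.total_qaly - tc.total_qaly))
    return pairs


@dataclass
class CEACCurve:
    """Probability the intervention is cost-effective at each
    willingness-to-pay value (incremental net monetary benefit >= 0)."""

    wtp: np.ndarray
    probability: np.ndarray

    def at(self, wtp_value: float) -> float:
        i = int(np.argmin(np.abs(self.wtp - wtp_value)))
        return float(self.probability[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


def pairs_to_array(pairs: Sequence[CEPair]) -> np.ndarray:
    return np.asarray([(p.delta_cost, p.delta_qaly) for p in pairs], dtype=float)


def ceac(pairs: Sequence[CEPair], wtp_grid=None) -> CEACCurve:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid
    (default 0 to 50,000 GBP/QALY in 500 steps).  At each threshold the
    probability is the fraction of draws with nonnegative incremental net
    monetary benefit ``wtp * dQ - dC`` (ties count as cost-effective)."""
    if not len(pairs):
        raise ValueError("pairs must be nonempty")
    wtp_grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("willingness-to-pay grid must be nonempty")
    arr = pairs_to_array(pairs)
    nmb = wtp_grid[:, None] * arr[None, :, 1] - arr[None, :, 0]
    return CEACCurve(wtp_grid, (nmb >= 0).mean(axis=1))


def probability_cost_effective(pairs: Sequence[CEPair], wtp: float) -> float:
    arr = pairs_to_array(pairs)
    return float((wtp * arr[:, 1] - arr[:, 0] >= 0).mean())


# ---------------------------------------------------------------------------
# One-way sensitivity and threshold analyses
# ---------------------------------------------------------------------------

def one_way_sensitivity(
    base: ParameterSet,
    param_path: str,
    values: Sequence[float],
    life_table=None,
    profiles=None,
) -> pd.DataFrame:
    """Deterministic re-run of the model for each value of one parameter,
    all other inputs at base.  Columns mirror the standard reporting layout:
    value, cost difference, QALY difference, ICER."""
    life_table, profiles = _default_inputs(base, life_table, profiles)
    rows = []
    for v in values:
        ps = base.copy()
        set_by_path(ps, param_path, v)
        ps.validate()
        ti, tc = _evaluate_strategies(ps, life_table, profiles)
        res = icer(ti, tc)
        rows.append(
            {
                "value": v,
                "cost_difference": res.delta_cost,
                "qaly_difference": res.delta_qaly,
                "icer": res.value,
            }
        )
    return pd.DataFrame(rows)


def _icer_at(base, param_path, value, life_table, profiles, _cache={}):
    ps = base.copy()
    set_by_path(ps, param_path, value)
    ps.validate()
    ti, tc = _evaluate_strategies(ps, life_table, profiles)
    return icer(ti, tc).value


def threshold_search(
    base: ParameterSet,
    param_path: str,
    wtp: float,
    bracket: tuple[float, float],
    tol: float = 1.0,
    xtol: float = 1e-6,
    max_iter: int = 100,
    life_table=None,
    profiles=None,
) -> float:
    """Bisection for the parameter value at which the ICER equals the
    willingness-to-pay threshold.

    The ICER is required to be (empirically) monotone over the bracket —
    checked on a 5-point scan — and the endpoint ICERs must straddle `wtp`.
    Stops when |ICER - wtp| <= `tol` (GBP/QALY, default 1) or the bracket
    width falls below `xtol`.
    """
    life_table, profiles = _default_inputs(base, life_table, profiles)
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError("bracket must satisfy lo < hi")
    scan_x = np.linspace(lo, hi, 5)
    scan_f = [_icer_at(base, param_path, x, life_table, profiles) for x in scan_x]
    diffs = np.diff(scan_f)
    if not (np.all(diffs >= -abs(tol)) or np.all(diffs <= abs(tol))):
        raise ValueError(
            f"ICER is not monotone over bracket {bracket} for {param_path}: "
            f"scan values {np.round(scan_f, 2).tolist()}"
        )
    f_lo, f_hi = scan_f[0], scan_f[-1]
    if (f_lo - wtp) * (f_hi - wtp) > 0:
        raise ValueError(
            f"ICER does not cross wtp={wtp} over bracket {bracket} for "
            f"{param_path}: ICER({lo})={f_lo:.2f}, ICER({hi})={f_hi:.2f}"
        )
    increasing = f_hi > f_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = _icer_at(base, param_path, mid, life_table, profiles)
        if abs(f_mid - wtp) <= tol or (hi - lo) < xtol:
            return mid
        if (f_mid > wtp) == increasing:
            hi = mid
        else:
            lo = mid
    logger.warning("threshold search hit max_iter=%d for %s", max_iter, param_path)
    return 0.5 * (lo + hi)
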