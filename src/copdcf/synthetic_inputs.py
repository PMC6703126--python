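"""Synthetic stand-ins for externally sourced model inputs.

The decision model needs three inputs that are not printed in the parameter
tables: an age/sex life table for background mortality, age profiles scaling
the age-50 disease parameters to other ages, and the COPD adjustment that
removes COPD-attributable deaths from all-cause mortality (COPD states carry
their own mortality, so leaving it in would double count).  This module
generates parametric, deterministic stand-ins — a Gompertz–Makeham life
table and log-linear age multipliers — so the full pipeline runs and is
testable without any external download.  It also packages the default
parameter set (point estimates plus uncertainty distributions).

All stand-ins are synthetic: they emulate the shape of national life tables
and age-dependent disease rates, not any particular published vintage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import DistributionSpec, ParameterSet, validate_parameters

logger = logging.getLogger(__name__)

__all__ = [
    "LifeTable",
    "AgeProfile",
    "make_life_table",
    "copd_adjusted_mortality",
    "make_age_profiles",
    "default_parameter_pack",
    "default_model_inputs",
]


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------

@dataclass
class LifeTable:
    """Annual all-cause death probabilities per integer age and sex.

    The terminal age carries probability 1 by convention, so no cohort
    member survives past the end of the table; lookups beyond the supported
    range clamp to the nearest row (logged once).
    """

    ages: np.ndarray
    qx_male: np.ndarray
    qx_female: np.ndarray
    _warned: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.qx_male = np.asarray(self.qx_male, dtype=float)
        self.qx_female = np.asarray(self.qx_female, dtype=float)
        for name, qx in (("male", self.qx_male), ("female", self.qx_female)):
            if qx.shape != self.ages.shape:
                raise ValueError(f"life table {name} column length mismatch")
            if np.any(qx <= 0) or np.any(qx > 1):
                raise ValueError(f"life table {name} probabilities must be in (0, 1]")

    def _index(self, age: float) -> int:
        i = int(math.floor(age)) - int(self.ages[0])
        if i < 0 or i >= len(self.ages):
            if not self._warned:
                logger.warning(
                    "age %.1f outside life-table support [%d, %d]; clamping",
                    age, self.ages[0], self.ages[-1],
                )
                self._warned = True
            i = min(max(i, 0), len(self.ages) - 1)
        return i

    def annual_probability(self, age: float, male_fraction: float = 0.5) -> float:
        """Sex-blended annual death probability at (the integer part of) `age`."""
        i = self._index(age)
        return float(
            male_fraction * self.qx_male[i]
            + (1.0 - male_fraction) * self.qx_female[i]
        )

    def to_frame(self) -> pd.DataFrame:
        """Long format (age, sex, qx), one row per age and sex."""
        return pd.DataFrame(
            {
                "age": np.concatenate([self.ages, self.ages]),
                "sex": ["male"] * len(self.ages) + ["female"] * len(self.ages),
                "qx": np.concatenate([self.qx_male, self.qx_female]),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        m = df[df["sex"] == "male"].sort_values("age")
        f = df[df["sex"] == "female"].sort_values("age")
        if not np.array_equal(m["age"].to_numpy(), f["age"].to_numpy()):
            raise ValueError(f"life table {path}: male/female age grids differ")
        return cls(m["age"].to_numpy(), m["qx"].to_numpy(), f["qx"].to_numpy())


def make_life_table(
    makeham_a: float = 2.0e-4,
    gompertz_b: float = 2.4e-5,
    gompertz_c: float = 1.10,
    sex_hazard_ratio: float = 0.60,
    age_min: int = 40,
    age_max: int = 100,
) -> LifeTable:
    """Deterministic Gompertz–Makeham life table.

    The male hazard is ``mu(t) = a + b * c**t``; the female hazard is
    ``sex_hazard_ratio`` times the male hazard.  Annual death probabilities
    come from the exact hazard integral over each year of age,
    ``q_x = 1 - exp(-int_x^{x+1} mu)``, so the survival curve implied by the
    table equals ``exp(-cumulative hazard)`` identically.  Defaults give a
    male annual death probability of about 0.003 at age 50, roughly doubling
    every 7–8 years, resembling a contemporary high-income national table.
    """
    if makeham_a < 0 or gompertz_b < 0 or gompertz_c <= 0 or sex_hazard_ratio <= 0:
        raise ValueError("life-table parameters must be positive")
    ages = np.arange(age_min, age_max + 1)

    def _qx(ratio: float) -> np.ndarray:
        if gompertz_b > 0 and gompertz_c != 1.0:
            integral = makeham_a + gompertz_b * (
                gompertz_c ** (ages + 1) - gompertz_c ** ages
            ) / math.log(gompertz_c)
        else:
            integral = np.full(ages.shape, makeham_a + gompertz_b, dtype=float)
        q = 1.0 - np.exp(-ratio * integral)
        if np.any(q >= 1.0):
            logger.warning("life-table hazard saturates before terminal age; capped")
        q = np.minimum(q, 1.0)
        q[-1] = 1.0  # terminal age: certain death by convention
        return q

    return LifeTable(ages, _qx(1.0), _qx(sex_hazard_ratio))


def copd_adjusted_mortality(
    life_table: LifeTable,
    copd_death_rate,
    prevalence: float,
) -> LifeTable:
    """Remove the COPD-attributable share from all-cause mortality.

    The all-cause probability mixes COPD and non-COPD deaths:
    ``q_all = prevalence * q_copd + (1 - prevalence) * q_free``.  Solving for
    the disease-free probability gives
    ``q_free = (q_all - prevalence * q_copd) / (1 - prevalence)``, floored at
    0 (logged if the floor binds).  ``copd_death_rate`` may be a scalar or a
    per-age array on the table's support.
    """
    if not 0.0 <= prevalence < 1.0:
        raise ValueError("prevalence must be in [0, 1)")
    q_copd = np.broadcast_to(
        np.asarray(copd_death_rate, dtype=float), life_table.ages.shape
    )

    def _adjust(q_all: np.ndarray) -> np.ndarray:
        adj = (q_all - prevalence * q_copd) / (1.0 - prevalence)
        if np.any(adj <= 0):
            logger.warning("COPD-adjusted mortality floored at a positive minimum")
            adj = np.maximum(adj, 1e-12)
        adj[-1] = 1.0
        return np.minimum(adj, 1.0)

    return LifeTable(
        life_table.ages, _adjust(life_table.qx_male), _adjust(life_table.qx_female)
    )


# ---------------------------------------------------------------------------
# Age profiles
# ---------------------------------------------------------------------------

@dataclass
class AgeProfile:
    """Log-linear age multipliers anchored at a reference age.

    ``multiplier(name, age) = exp(slope[name] * (age - reference_age))``,
    so the multiplier is exactly 1 at the reference age for every slope.
    Unknown names behave as slope 0 (age-constant).  Default slopes are 0:
    the age-50 point estimates apply at every age unless a profile is
    explicitly switched on, keeping any departure from the printed inputs
    opt-in and visible.
    """

    reference_age: float = 50.0
    slopes: dict[str, float] = field(default_factory=dict)

    def multiplier(self, name: str, age: float) -> float:
        slope = self.slopes.get(name, 0.0)
        if slope == 0.0:
            return 1.0
        return math.exp(slope * (age - self.reference_age))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": list(self.slopes), "slope": list(self.slopes.values())}
        )


PROFILE_NAMES = ("incidence", "progression", "copd_mortality")


def make_age_profiles(
    slopes: dict[str, float] | None = None, reference_age: float = 50.0
) -> AgeProfile:
    """Age profiles for COPD incidence, GOLD progression and COPD-state
    mortality; missing entries default to slope 0 (age-constant)."""
    slopes = dict(slopes or {})
    unknown = set(slopes) - set(PROFILE_NAMES)
    if unknown:
        raise ValueError(f"unknown age-profile names: {sorted(unknown)}")
    for name in PROFILE_NAMES:
        slopes.setdefault(name, 0.0)
        if not math.isfinite(slopes[name]):
            raise ValueError(f"age-profile slope for {name} must be finite")
    return AgeProfile(reference_age=reference_age, slopes=slopes)


# ---------------------------------------------------------------------------
# Packaged defaults
# ---------------------------------------------------------------------------

def _beta(point: float, alpha: float, beta: float, negate: bool = False) -> DistributionSpec:
    return DistributionSpec("beta", point, alpha=alpha, beta=beta, negate=negate)


def _beta_ess(point: float, ess: float, negate: bool = False) -> DistributionSpec:
    p = abs(point)
    return DistributionSpec(
        "beta", p, alpha=p * ess, beta=(1.0 - p) * ess, negate=negate
    )


def _gamma(point: float, shape: float) -> DistributionSpec:
    # Rate chosen so the mean equals the point estimate; `shape` fixes the
    # coefficient of variation (CV = 1/sqrt(shape)).
    return DistributionSpec("gamma", point, alpha=shape, lam=shape / point)


def _lognormal(point: float, sigma: float) -> DistributionSpec:
    return DistributionSpec("lognormal", point, sigma=sigma)


def default_parameter_pack() -> ParameterSet:
    """The packaged base case: every point estimate of the published input
    tables plus its probabilistic-sensitivity-analysis distribution.

    Beta distributions with published success/failure counts are used where
    available; remaining probabilities and utilities get beta distributions
    at the configurable effective sample size, costs get gamma distributions
    rescaled so their mean equals the point estimate (preserving the stated
    coefficient of variation where shape parameters were published), and
    odds ratios get lognormal distributions with a configurable log-scale
    sigma (their dispersion is not published).
    """
    ps = ParameterSet()
    ess = ps.psa.beta_ess
    cost_shape = ps.psa.cost_shape
    or_sigma = ps.psa.or_log_sigma
    nh = ps.natural_history

    dists: dict[str, DistributionSpec] = {
        # starting cohort (published counts)
        "cohort.male_fraction": _beta(0.527, 5999, 5394),
        "cohort.frac_asymptomatic": _beta(0.430, 364, 482),
        "cohort.frac_symptomatic": _beta(0.482, 364, 482),
        "cohort.frac_undiagnosed": _beta(0.088, 74, 772),
        "cohort.gold_split[0]": _beta(0.690, 58, 26),
        "cohort.gold_split[1]": _beta(0.274, 23, 61),
        "cohort.gold_split[2]": _beta(0.036, 3, 81),
        # natural history
        "natural_history.p_symptom_onset": _beta(0.020, 135, 6775),
        "natural_history.p_copd_incidence": _beta(0.006, 55, 9945),
        "natural_history.incident_gold1_fraction": _beta(0.722, 44, 17),
        "natural_history.p_exacerbation_fatality": _beta_ess(0.0703, ess),
        # care pathway
        "care.p_routine_diagnosis": _beta(0.008, 337, 41692),
        "care.p_treatment_initiation": _beta(0.293, 3972, 9585),
        # case-finding cascade
        "case_finding.p_receive": _beta(0.999, 12175, 1),
        "case_finding.p_respond": _beta(0.355, 846, 1572),
        "case_finding.p_attend": _beta(0.661, 559, 287),
        "case_finding.cost_questionnaire": DistributionSpec(
            "gamma", 4.01, alpha=99, lam=99 / 4.01
        ),
        "case_finding.cost_spirometry": DistributionSpec(
            "gamma", 55.27, alpha=24, lam=24 / 55.27
        ),
        # treatment effects
        "treatment.or_mortality": _lognormal(0.98, or_sigma),
        "treatment.or_exacerbation": _lognormal(0.85, or_sigma),
        "treatment.or_progression": _lognormal(0.85, or_sigma),
        "treatment.utility_gain": _beta_ess(0.0367, ess),
        # utilities (published counts where available)
        "utilities.asymptomatic": _beta(0.8394, 1522, 291),
        "utilities.symptomatic": _beta(0.7549, 8817, 2862),
    }
    for g in range(4):
        dists[f"utilities.gold[{g}]"] = _beta_ess(float(ps.utilities.gold[g]), ess)
        dists[f"utilities.exacerbation_disutility[{g}]"] = _beta_ess(
            float(ps.utilities.exacerbation_disutility[g]), ess, negate=True
        )
        dists[f"natural_history.p_exacerbation[{g}]"] = _beta_ess(
            float(nh.p_exacerbation[g]), ess
        )
        dists[f"costs.scheduled_care[{g}]"] = _gamma(
            float(ps.costs.scheduled_care[g]), cost_shape
        )
        dists[f"costs.medication[{g}]"] = _gamma(
            float(ps.costs.medication[g]), cost_shape
        )
    dists["costs.exacerbation_episode"] = _gamma(
        float(ps.costs.exacerbation_episode), cost_shape
    )
    # annual GOLD matrix: independent beta per nonzero off-diagonal entry
    # (stay recomputed as the residual after sampling)
    gm = np.asarray(nh.gold_matrix)
    for r in range(4):
        for c in range(5):
            if c == r or gm[r, c] == 0.0:
                continue
            dists[f"natural_history.gold_matrix[{r},{c}]"] = _beta_ess(
                float(gm[r, c]), ess
            )

    ps.distributions = dists
    validate_parameters(ps)
    return ps


def stage_weighted_copd_mortality(ps: ParameterSet) -> float:
    """Average annual COPD-state death probability, weighted by the prevalent
    GOLD-stage mix of the starting cohort (no mass in GOLD 4)."""
    weights = np.append(np.asarray(ps.cohort.gold_split, dtype=float), 0.0)
    death_col = np.asarray(ps.natural_history.gold_matrix, dtype=float)[:, 4]
    return float(weights @ death_col)


def default_model_inputs(
    ps: ParameterSet | None = None,
    life_table: LifeTable | None = None,
    profiles: AgeProfile | None = None,
) -> tuple[LifeTable, AgeProfile]:
    """The standard input pipeline: synthetic life table, adjusted to remove
    the COPD-attributable mortality share, plus default (flat) age profiles."""
    if ps is None:
        ps = default_parameter_pack()
    if life_table is None:
        life_table = make_life_table()
    adjusted = copd_adjusted_mortality(
        life_table,
        stage_weighted_copd_mortality(ps),
        ps.cohort.copd_prevalence,
    )
    if profiles is None:
        profiles = make_age_profiles()
    return adjusted, profiles
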