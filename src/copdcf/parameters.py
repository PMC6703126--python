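"""Model inputs and the probability/rate/odds transformations they feed.

Every input of the decision model lives in a :class:`ParameterSet` — starting
cohort composition, natural history, care pathway, treatment effects,
utilities, costs and analysis settings — together with a map of uncertainty
distributions used for probabilistic sensitivity analysis (second-order Monte
Carlo).  Each parameter is addressable by a dotted path (e.g.
``"treatment.or_progression"`` or ``"natural_history.gold_matrix[2,3]"``) so
one-way sensitivity and threshold analyses can perturb any single input.
"""

from __future__ import annotations

import copy
import logging
import math
import re
from dataclasses import dataclass, field, fields, is_dataclass

import numpy as np
import yaml

from .case_finding import StrategyConfig

logger = logging.getLogger(__name__)

__all__ = [
    "DistributionSpec",
    "ParameterSet",
    "distribution_mean",
    "annual_to_cycle_prob",
    "apply_odds_ratio",
    "sample_parameter_set",
    "load_parameters",
    "get_by_path",
    "set_by_path",
    "params_to_dict",
    "params_from_dict",
    "parameter_sets_equal",
]


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------

_KINDS = ("beta", "gamma", "lognormal", "fixed")


@dataclass
class DistributionSpec:
    """Uncertainty distribution for a single scalar parameter.

    kind
        ``beta`` (alpha/beta counts, support [0, 1]), ``gamma`` (shape alpha
        and rate lam, support >= 0), ``lognormal`` (median ``point`` with
        log-scale dispersion ``sigma``, support > 0) or ``fixed``.
    point
        Deterministic point estimate, always on the natural scale of the
        parameter.
    negate
        Draw the magnitude from the distribution and flip the sign —
        used for disutilities, which are negative but beta-distributed in
        magnitude.
    """

    kind: str
    point: float
    alpha: float | None = None
    beta: float | None = None
    lam: float | None = None
    sigma: float | None = None
    negate: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "beta":
            if self.alpha is None or self.beta is None or self.alpha <= 0 or self.beta <= 0:
                raise ValueError(
                    f"beta distribution requires alpha > 0 and beta > 0, got "
                    f"alpha={self.alpha}, beta={self.beta}"
                )
        elif self.kind == "gamma":
            if self.alpha is None or self.lam is None or self.alpha <= 0 or self.lam <= 0:
                raise ValueError(
                    f"gamma distribution requires alpha > 0 and lam > 0, got "
                    f"alpha={self.alpha}, lam={self.lam}"
                )
        elif self.kind == "lognormal":
            if self.point <= 0:
                raise ValueError("lognormal point estimate must be > 0")
            if self.sigma is None or self.sigma < 0:
                raise ValueError("lognormal distribution requires sigma >= 0")

    def mean(self) -> float:
        """Distribution mean: beta -> a/(a+b); gamma -> a/lam; lognormal and
        fixed -> the point estimate (the lognormal is parameterised by its
        median point value)."""
        if self.kind == "beta":
            m = self.alpha / (self.alpha + self.beta)
        elif self.kind == "gamma":
            m = self.alpha / self.lam
        else:
            m = self.point
        return -m if self.negate else m

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "beta":
            x = rng.beta(self.alpha, self.beta)
        elif self.kind == "gamma":
            x = rng.gamma(self.alpha, 1.0 / self.lam)
        elif self.kind == "lognormal":
            x = self.point * math.exp(rng.normal(0.0, self.sigma))
        else:
            x = self.point
        return -x if self.negate else x

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "point": float(self.point)}
        for k in ("alpha", "beta", "lam", "sigma"):
            v = getattr(self, k)
            if v is not None:
                d[k] = float(v)
        if self.negate:
            d["negate"] = True
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        return cls(**d)


def distribution_mean(spec: DistributionSpec) -> float:
    """Mean of a parameter's uncertainty distribution (see
    :meth:`DistributionSpec.mean`)."""
    return spec.mean()


# ---------------------------------------------------------------------------
# Probability transformations
# ---------------------------------------------------------------------------

def annual_to_cycle_prob(p_annual, cycle_years: float):
    """Convert an annual probability to a per-cycle probability under a
    constant-rate assumption: ``1 - (1 - p)**cycle_years``.

    Accepts scalars or arrays.  Four independent quarters recover the annual
    probability exactly: ``1 - (1 - p_q)**4 == p``.
    """
    p = np.asarray(p_annual, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"annual probability {p_annual} outside [0, 1]")
    if not 0 < cycle_years <= 1:
        raise ValueError(f"cycle_years={cycle_years} must be in (0, 1]")
    out = 1.0 - (1.0 - p) ** cycle_years
    return float(out) if np.isscalar(p_annual) else out


def apply_odds_ratio(p, or_value):
    """Modify a probability by an odds ratio on the odds scale.

    Returns ``OR*p/(1-p) / (1 + OR*p/(1-p))``.  Monotone increasing in both
    arguments; composing ORs a then b equals applying a*b.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError(f"probability {p} outside [0, 1]")
    if np.any(p_arr == 1.0):
        raise ValueError("cannot apply an odds ratio at p = 1 (infinite odds)")
    if np.any(np.asarray(or_value) <= 0):
        raise ValueError(f"odds ratio must be > 0, got {or_value}")
    odds = or_value * p_arr / (1.0 - p_arr)
    out = odds / (1.0 + odds)
    return float(out) if np.isscalar(p) and np.isscalar(or_value) else out


# ---------------------------------------------------------------------------
# Parameter groups
# ---------------------------------------------------------------------------

def _arr(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class StartingCohort:
    start_age: float = 50.0
    male_fraction: float = 0.527
    frac_asymptomatic: float = 0.430
    frac_symptomatic: float = 0.482
    frac_undiagnosed: float = 0.088
    gold_split: np.ndarray = field(
        default_factory=lambda: _arr([0.690, 0.274, 0.036])
    )  # GOLD 1-3 split of prevalent undiagnosed COPD
    copd_prevalence: float = 0.09  # background prevalence for mortality adjustment


@dataclass
class NaturalHistory:
    p_symptom_onset: float = 0.020        # annual, asymptomatic -> symptomatic
    p_copd_incidence: float = 0.006       # annual, symptomatic -> COPD (age 50)
    incident_gold1_fraction: float = 0.722  # incident cases starting in GOLD 1
    # Annual GOLD transition matrix, rows GOLD 1-4, columns GOLD 1-4 + dead.
    # Only off-diagonal entries are consumed (stay = residual after
    # rate conversion), so the printed diagonal never needs renormalising.
    gold_matrix: np.ndarray = field(
        default_factory=lambda: _arr(
            [
                [0.9047, 0.0876, 0.0000, 0.0000, 0.0077],
                [0.0510, 0.9001, 0.0362, 0.0000, 0.0128],
                [0.0000, 0.1044, 0.8368, 0.0324, 0.0265],
                [0.0000, 0.0000, 0.0936, 0.8187, 0.0877],
            ]
        )
    )
    p_exacerbation: np.ndarray = field(
        default_factory=lambda: _arr([0.027, 0.076, 0.272, 0.348])
    )  # annual severe (hospitalised) exacerbation probability per GOLD stage
    p_exacerbation_fatality: float = 0.0703  # in-episode case fatality


@dataclass
class CarePathway:
    p_routine_diagnosis: float = 0.008      # annual, undiagnosed -> diagnosed
    p_treatment_initiation: float = 0.293   # annual, diagnosed -> treated


@dataclass
class TreatmentEffects:
    or_mortality: float = 0.98
    or_exacerbation: float = 0.85
    or_progression: float = 0.85
    utility_gain: float = 0.0367


@dataclass
class Utilities:
    asymptomatic: float = 0.8394
    symptomatic: float = 0.7549
    gold: np.ndarray = field(
        default_factory=lambda: _arr([0.7197, 0.7013, 0.6798, 0.5855])
    )
    exacerbation_disutility: np.ndarray = field(
        default_factory=lambda: _arr([-0.2398, -0.2337, -0.2265, -0.1951])
    )
    # Duration weighting of the exacerbation utility loss: 50% of the
    # disutility for one month plus 25% for each of two further months,
    # i.e. one full-disutility month = 1/12 QALY per unit disutility.
    exacerbation_duration_multiplier: float = 1.0


@dataclass
class Costs:
    scheduled_care: np.ndarray = field(
        default_factory=lambda: _arr([164.56, 267.06, 394.01, 541.06])
    )  # annual GP + scheduled hospital care per diagnosed GOLD stage (GBP)
    medication: np.ndarray = field(
        default_factory=lambda: _arr([485.16, 567.84, 735.96, 824.52])
    )  # annual inhaled maintenance medication per treated GOLD stage (GBP)
    exacerbation_episode: float = 2263.00  # inpatient stay per severe episode


@dataclass
class AnalysisSettings:
    discount_rate: float = 0.035
    cycle_years: float = 0.25
    horizon_years: float = 50.0


@dataclass
class PsaSettings:
    """Dispersion assumptions for inputs whose uncertainty the sources do not
    quantify: log-scale sigma for odds ratios, an effective sample size for
    beta-distributed probabilities/utilities without published counts, and a
    gamma shape for costs without published shape (CV = 1/sqrt(shape))."""

    or_log_sigma: float = 0.1
    beta_ess: float = 400.0
    cost_shape: float = 25.0


@dataclass
class ParameterSet:
    cohort: StartingCohort = field(default_factory=StartingCohort)
    natural_history: NaturalHistory = field(default_factory=NaturalHistory)
    care: CarePathway = field(default_factory=CarePathway)
    treatment: TreatmentEffects = field(default_factory=TreatmentEffects)
    utilities: Utilities = field(default_factory=Utilities)
    costs: Costs = field(default_factory=Costs)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    case_finding: StrategyConfig = field(default_factory=StrategyConfig)
    psa: PsaSettings = field(default_factory=PsaSettings)
    distributions: dict[str, DistributionSpec] = field(default_factory=dict)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def validate(self) -> "ParameterSet":
        validate_parameters(self)
        return self


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_PROB_FIELDS = [
    "cohort.male_fraction",
    "cohort.frac_asymptomatic",
    "cohort.frac_symptomatic",
    "cohort.frac_undiagnosed",
    "cohort.copd_prevalence",
    "natural_history.p_symptom_onset",
    "natural_history.p_copd_incidence",
    "natural_history.incident_gold1_fraction",
    "natural_history.p_exacerbation_fatality",
    "care.p_routine_diagnosis",
    "care.p_treatment_initiation",
]


def validate_parameters(ps: ParameterSet) -> None:
    """Check every structural invariant, raising ValueError naming the
    offending key and constraint."""
    for path in _PROB_FIELDS:
        v = get_by_path(ps, path)
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{path}={v} must be a probability in [0, 1]")
    for name, arr in [
        ("cohort.gold_split", ps.cohort.gold_split),
        ("natural_history.p_exacerbation", ps.natural_history.p_exacerbation),
    ]:
        arr = np.asarray(arr)
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(f"{name} entries must be probabilities in [0, 1]")
    split_sum = float(
        ps.cohort.frac_asymptomatic
        + ps.cohort.frac_symptomatic
        + ps.cohort.frac_undiagnosed
    )
    if abs(split_sum - 1.0) > 5e-3:
        raise ValueError(
            f"cohort starting fractions sum to {split_sum}, expected 1"
        )
    if abs(float(np.sum(ps.cohort.gold_split)) - 1.0) > 5e-3:
        raise ValueError("cohort.gold_split must sum to 1")
    gm = np.asarray(ps.natural_history.gold_matrix, dtype=float)
    if gm.shape != (4, 5):
        raise ValueError("natural_history.gold_matrix must be 4x5 (GOLD1-4 x GOLD1-4+dead)")
    if np.any(gm < 0) or np.any(gm > 1):
        raise ValueError("natural_history.gold_matrix entries must be in [0, 1]")
    for r in range(4):
        off = gm[r].sum() - gm[r, r]
        if off > 1.0 + 1e-9:
            raise ValueError(
                f"natural_history.gold_matrix row {r + 1} off-diagonal mass "
                f"{off:.4f} exceeds 1"
            )
    for name, arr in [
        ("costs.scheduled_care", ps.costs.scheduled_care),
        ("costs.medication", ps.costs.medication),
        ("costs.exacerbation_episode", ps.costs.exacerbation_episode),
    ]:
        if np.any(np.asarray(arr) < 0):
            raise ValueError(f"{name} must be >= 0")
    for name, v in [
        ("utilities.asymptomatic", ps.utilities.asymptomatic),
        ("utilities.symptomatic", ps.utilities.symptomatic),
    ]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} must be in [0, 1]")
    ug = np.asarray(ps.utilities.gold)
    if np.any(ug < 0) or np.any(ug > 1):
        raise ValueError("utilities.gold entries must be in [0, 1]")
    if np.any(np.asarray(ps.utilities.exacerbation_disutility) > 0):
        raise ValueError("utilities.exacerbation_disutility entries must be <= 0")
    if not 0.0 <= ps.treatment.utility_gain <= 1.0:
        raise ValueError("treatment.utility_gain must be in [0, 1]")
    for name in ("or_mortality", "or_exacerbation", "or_progression"):
        v = getattr(ps.treatment, name)
        if v <= 0:
            raise ValueError(f"treatment.{name}={v} must be > 0")
    if ps.analysis.discount_rate < 0:
        raise ValueError("analysis.discount_rate must be >= 0")
    if not 0 < ps.analysis.cycle_years <= 1:
        raise ValueError("analysis.cycle_years must be in (0, 1]")
    if ps.analysis.horizon_years <= 0:
        raise ValueError("analysis.horizon_years must be positive")
    ps.case_finding.validate(ps.analysis.cycle_years)
    logger.debug("parameter set validated: %d distributions", len(ps.distributions))


# ---------------------------------------------------------------------------
# Dotted-path access
# ---------------------------------------------------------------------------

_PATH_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_]*)(?:\[([0-9,\s]+)\])?$")


def _walk(obj, path: str):
    parts = path.split(".")
    for part in parts[:-1]:
        m = _PATH_RE.match(part)
        if m is None or m.group(2) is not None or not hasattr(obj, m.group(1)):
            raise KeyError(f"cannot resolve parameter path {path!r} at {part!r}")
        obj = getattr(obj, m.group(1))
    m = _PATH_RE.match(parts[-1])
    if m is None or not hasattr(obj, m.group(1)):
        raise KeyError(f"cannot resolve parameter path {path!r}")
    idx = None
    if m.group(2) is not None:
        idx = tuple(int(i) for i in m.group(2).split(","))
        if len(idx) == 1:
            idx = idx[0]
    return obj, m.group(1), idx


def get_by_path(ps: ParameterSet, path: str):
    obj, name, idx = _walk(ps, path)
    val = getattr(obj, name)
    if idx is not None:
        return float(np.asarray(val)[idx])
    return val


def set_by_path(ps: ParameterSet, path: str, value) -> None:
    obj, name, idx = _walk(ps, path)
    if idx is not None:
        arr = np.asarray(getattr(obj, name), dtype=float)
        arr[idx] = value
        setattr(obj, name, arr)
    else:
        current = getattr(obj, name)
        if isinstance(current, np.ndarray):
            value = np.asarray(value, dtype=float)
            if value.shape != current.shape:
                raise ValueError(
                    f"{path}: expected shape {current.shape}, got {value.shape}"
                )
        elif isinstance(current, bool):
            value = bool(value)
        elif isinstance(current, (int, float)):
            value = float(value)
        setattr(obj, name, value)


# ---------------------------------------------------------------------------
# PSA sampling
# ---------------------------------------------------------------------------

def sample_parameter_set(
    base: ParameterSet, seed: int | np.random.Generator
) -> ParameterSet:
    """Draw one probabilistic-sensitivity-analysis parameter set.

    Every path in ``base.distributions`` is drawn independently; fixed
    specs return the point estimate.  Joint structure is restored
    afterwards: the three starting-cohort fractions and the prevalent GOLD
    split are renormalised to sum to 1, and each annual GOLD matrix row has
    its stay probability recomputed as the residual of the sampled
    off-diagonal entries (rescaled if they exceed 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = base.copy()
    for path in base.distributions:
        out_value = base.distributions[path].sample(rng)
        set_by_path(out, path, out_value)

    sampled = set(base.distributions)
    if any(p.startswith("cohort.frac_") for p in sampled):
        c = out.cohort
        total = c.frac_asymptomatic + c.frac_symptomatic + c.frac_undiagnosed
        c.frac_asymptomatic /= total
        c.frac_symptomatic /= total
        c.frac_undiagnosed /= total
    if any(p.startswith("cohort.gold_split") for p in sampled):
        c = out.cohort
        c.gold_split = np.asarray(c.gold_split, dtype=float)
        c.gold_split /= c.gold_split.sum()

    if any(p.startswith("natural_history.gold_matrix") for p in sampled):
        gm = np.asarray(out.natural_history.gold_matrix, dtype=float)
        for r in range(4):
            off = gm[r].sum() - gm[r, r]
            if off > 1.0:
                logger.warning(
                    "sampled GOLD matrix row %d off-diagonal mass %.4f > 1; "
                    "renormalised",
                    r + 1,
                    off,
                )
                gm[r] *= 1.0 / off
                off = 1.0
            gm[r, r] = 1.0 - off
        out.natural_history.gold_matrix = gm

    validate_parameters(out)
    return out


# ---------------------------------------------------------------------------
# Serialisation and loading
# ---------------------------------------------------------------------------

_GROUPS = (
    "cohort",
    "natural_history",
    "care",
    "treatment",
    "utilities",
    "costs",
    "analysis",
    "case_finding",
    "psa",
)


def _group_to_dict(obj) -> dict:
    d = {}
    for f in fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, np.ndarray):
            d[f.name] = v.tolist()
        else:
            d[f.name] = v
    return d


def params_to_dict(ps: ParameterSet) -> dict:
    d = {g: _group_to_dict(getattr(ps, g)) for g in _GROUPS}
    d["distributions"] = {k: v.to_dict() for k, v in ps.distributions.items()}
    return d


def _apply_overrides(obj, overrides: dict, prefix: str) -> None:
    valid = {f.name for f in fields(obj)}
    for key, value in overrides.items():
        if key not in valid:
            raise KeyError(f"unknown parameter key {prefix}{key!r}")
        current = getattr(obj, key)
        if is_dataclass(current) and isinstance(value, dict):
            _apply_overrides(current, value, f"{prefix}{key}.")
        elif isinstance(current, np.ndarray):
            value = np.asarray(value, dtype=float)
            if value.shape != current.shape:
                raise ValueError(
                    f"{prefix}{key}: expected shape {current.shape}, "
                    f"got {value.shape}"
                )
            setattr(obj, key, value)
        elif isinstance(current, bool):
            setattr(obj, key, bool(value))
        elif isinstance(current, float):
            setattr(obj, key, float(value))
        else:
            setattr(obj, key, value)


def params_from_dict(d: dict, base: ParameterSet | None = None) -> ParameterSet:
    if base is None:
        from .synthetic_inputs import default_parameter_pack

        base = default_parameter_pack()
    ps = base.copy()
    d = dict(d or {})
    dists = d.pop("distributions", None)
    for key, value in d.items():
        if key not in _GROUPS:
            raise KeyError(f"unknown parameter group {key!r}")
        if not isinstance(value, dict):
            raise ValueError(f"parameter group {key!r} must be a mapping")
        _apply_overrides(getattr(ps, key), value, f"{key}.")
    if dists is not None:
        ps.distributions = {
            k: DistributionSpec.from_dict(v) for k, v in dists.items()
        }
    validate_parameters(ps)
    return ps


def load_parameters(config_source=None) -> ParameterSet:
    """Build a validated :class:`ParameterSet`.

    ``config_source`` may be None (packaged defaults), a mapping of
    overrides, or a path to a YAML file of overrides.  Unknown keys are
    rejected with an error naming the key.
    """
    if config_source is None:
        data: dict = {}
    elif isinstance(config_source, dict):
        data = config_source
    else:
        with open(config_source, "r") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {config_source} must contain a mapping")
    ps = params_from_dict(data)
    logger.info(
        "loaded parameters: discount=%.3f horizon=%gy interval=%gy (%d overrides)",
        ps.analysis.discount_rate,
        ps.analysis.horizon_years,
        ps.case_finding.interval_years,
        len(data),
    )
    return ps


def save_parameters(ps: ParameterSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(ps), fh, sort_keys=False)


def parameter_sets_equal(
    a: ParameterSet, b: ParameterSet, rtol: float = 0.0, atol: float = 0.0
) -> bool:
    """Structural equality of two parameter sets (exact by default)."""

    def _eq(x, y) -> bool:
        if isinstance(x, dict):
            return set(x) == set(y) and all(_eq(x[k], y[k]) for k in x)
        if isinstance(x, (list, tuple, np.ndarray)):
            x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
            return x.shape == y.shape and np.allclose(x, y, rtol=rtol, atol=atol)
        if isinstance(x, float) and isinstance(y, float):
            return math.isclose(x, y, rel_tol=rtol, abs_tol=atol) or x == y
        return x == y

    return _eq(params_to_dict(a), params_to_dict(b))
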