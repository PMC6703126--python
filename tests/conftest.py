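import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import copdcf as cf

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def base_params() -> cf.ParameterSet:
    return cf.default_parameter_pack()


@pytest.fixture(scope="session")
def inputs(base_params):
    """(COPD-adjusted life table, default flat age profiles)."""
    return cf.default_model_inputs(base_params)


@pytest.fixture(scope="session")
def base_traces(base_params, inputs):
    """Deterministic base-case traces (intervention, comparator)."""
    lt, pr = inputs
    ti = cf.run_cohort(base_params, base_params.case_finding, lt, pr)
    tc = cf.run_cohort(base_params, cf.routine_care(base_params.case_finding), lt, pr)
    return ti, tc


@pytest.fixture(scope="session")
def psa_pairs(base_params, inputs):
    """A moderate probabilistic-sensitivity-analysis sample shared across
    tests (300 draws, fixed seed)."""
    lt, pr = inputs
    return cf.run_psa(base_params, n=300, seed=7, life_table=lt, profiles=pr)


@pytest.fixture()
def short_params(base_params) -> cf.ParameterSet:
    """Base parameters with a 10-year horizon for cheap property checks."""
    ps = base_params.copy()
    ps.analysis.horizon_years = 10.0
    return ps


def assert_occupancy_conserved(trace):
    sums = trace.occupancy.sum(axis=1)
    assert np.all(np.abs(sums - 1.0) < 1e-10)
    assert np.all(trace.occupancy >= -1e-12)
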