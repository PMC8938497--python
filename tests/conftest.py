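import pytest

from frdpop import (
    CaptureRecaptureCount,
    ParameterDistributions,
    PopulationState,
    VitalRateParams,
    derive_rates,
)


@pytest.fixture(scope="session")
def city_counts():
    return CaptureRecaptureCount("city_pooled", "city", 283, 272, 83)


@pytest.fixture(scope="session")
def suburb_counts():
    return CaptureRecaptureCount("suburb_pooled", "suburb", 635, 505, 103)


@pytest.fixture(scope="session")
def mean_params():
    return VitalRateParams(Q=1.0, Np=2.3, M=0.23, fm=0.3125, du1=1.0)


@pytest.fixture(scope="session")
def mean_rates(mean_params):
    return derive_rates(mean_params)


@pytest.fixture(scope="session")
def initial_state():
    return PopulationState(puppy_young=1547, adult=5234)


@pytest.fixture(scope="session")
def default_dists():
    return ParameterDistributions()


@pytest.fixture(scope="session")
def degenerate_dists():
    """Zero-spread distributions pinned at the mean parameter values."""
    return ParameterDistributions(q_sd=0.0, m_sd=0.0, np_low=2.3, np_high=2.3)
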