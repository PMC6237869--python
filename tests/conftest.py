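import pytest

from bittermr import SimulationConfig, harmonize_cohort, simulate_sample1, simulate_sample2


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale cohort: large enough for stable logistic contrasts."""
    return SimulationConfig(seed=11, n_sample2=8000)


@pytest.fixture(scope="session")
def sample1(small_config):
    return simulate_sample1(small_config)


@pytest.fixture(scope="session")
def sample2_small(small_config):
    return simulate_sample2(small_config)


@pytest.fixture(scope="session")
def sample2_large(default_config):
    return simulate_sample2(default_config)


@pytest.fixture(scope="session")
def harmonized_small(sample2_small):
    table, _ = harmonize_cohort(sample2_small)
    return table
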