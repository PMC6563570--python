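import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from readerstudy import (
    GenerativeParams,
    StudyConfig,
    assign_crossover,
    default_roster,
    simulate_annotations,
    simulate_study,
    simulate_times,
    simulate_truth,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> StudyConfig:
    """A scaled-down study: quick to simulate and analyze in every test."""
    return StudyConfig(n_cases=30, n_permutations=200, seed=11)


@pytest.fixture(scope="session")
def full_config() -> StudyConfig:
    """The default design: 8 readers x 115 cases x 2 sessions."""
    return StudyConfig(seed=5, n_permutations=500)


@pytest.fixture(scope="session")
def small_study(small_config):
    """(cases, readers, annotations) for the scaled-down study."""
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def full_study(full_config):
    return simulate_study(full_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
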