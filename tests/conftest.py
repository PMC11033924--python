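import numpy as np
import pytest

from gradmap import RunConfig, SimulationSpec, simulate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down cohort for integration tests: 60 parcels, 10+10 subjects."""
    return SimulationSpec(
        n_parcels=60, n_timepoints=120, n_per_group=(10, 10), seed=42
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    cohort, truth = simulate_cohort(small_spec)
    return cohort, truth


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()
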