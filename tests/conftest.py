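import numpy as np
import pytest

from caddsplice import SimulationConfig, compact_schema, default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_schema():
    return compact_schema()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_training_set():
    """A modest simulated training set shared across model tests."""
    from caddsplice import simulate_training_set

    config = SimulationConfig(
        n_variants=2000,
        seed=7,
        true_weights={"GerpN": 1.5, "bStatistic": -1.0, "mamPhCons": 0.8},
    )
    return config, simulate_training_set(config)
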