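import numpy as np
import pytest

from protstab import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest labeled cohort shared by pipeline-level tests."""
    cfg = SimulationConfig(n_stable=40, n_slow=20, n_fast=10, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_config():
    return SimulationConfig(
        n_stable=0, n_slow=5, n_fast=5, noise_sd=0.0, missing_prob=0.0, seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
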