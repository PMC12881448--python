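import numpy as np
import pytest

from edamic.synthsample import SimConfig, simulate_sample


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(height=64, width=64, duration=150.0, n_mito=2,
                     n_spheres=3, contact_rate=1.0, contact_duration=20.0,
                     n_ruffles=1, noise_sd=0.01, seed=3)


@pytest.fixture(scope="session")
def small_sample(small_config):
    return simulate_sample(small_config)


@pytest.fixture(scope="session")
def division_config():
    return SimConfig(height=64, width=64, duration=150.0, n_mito=2,
                     n_spheres=2, contact_rate=0.0, division_rate=1.5,
                     pre_constriction_window=8, n_ruffles=1,
                     noise_sd=0.01, seed=27)


@pytest.fixture(scope="session")
def division_sample(division_config):
    return simulate_sample(division_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
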