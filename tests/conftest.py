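import numpy as np
import pytest

import vmbsim as v


@pytest.fixture(scope="session")
def small_pop():
    """A desk-scale virtual population (300 BV+ patients from an 8k pool)."""
    return v.generate_population(pool_size=8_000, n=300, seed=11)


@pytest.fixture(scope="session")
def small_dose(small_pop):
    return v.calibrate_dose(small_pop)


@pytest.fixture(scope="session")
def tiny_pop():
    """A very small population (40 patients) for expensive sweeps."""
    return v.generate_population(pool_size=4_000, n=40, seed=7)


@pytest.fixture(scope="session")
def tiny_dose(tiny_pop):
    return v.calibrate_dose(tiny_pop)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
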