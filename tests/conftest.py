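import numpy as np
import pytest

from chronosig import synth


@pytest.fixture(scope="session")
def default_specs():
    return synth.default_class_specs()


@pytest.fixture(scope="session")
def small_cohort(default_specs):
    """Three-class cohort small enough for fast unit tests."""
    return synth.simulate_cohort(default_specs, 6, 120, seed=101).streams


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
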