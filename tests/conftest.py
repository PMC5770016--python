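import numpy as np
import pytest

from dentinchron import fixtures
from dentinchron.simulate import SimParams, simulate_micrograph


@pytest.fixture(scope="session")
def beluga_records():
    return fixtures.beluga_records()


@pytest.fixture(scope="session")
def beluga_summaries():
    return fixtures.beluga_summaries()


@pytest.fixture(scope="session")
def beluga_days():
    return fixtures.beluga_day_table()


@pytest.fixture(scope="session")
def small_micrograph():
    """One short synthetic GLG rendered once for the detection tests."""
    params = SimParams(seed=11, n_glgs=1, days_per_glg=120, field_height_um=30.0)
    image, truth = simulate_micrograph(params)
    return params, image, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
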