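import numpy as np
import pytest

from airburden.grid import PrecursorPollutantPair, SensitivityField, make_grid


@pytest.fixture
def small_grid():
    return make_grid(10, 12, 36.0, (0.0, 0.0))


@pytest.fixture
def pm_pair():
    return PrecursorPollutantPair("POC", "PM25")


@pytest.fixture
def o3_pair():
    return PrecursorPollutantPair("NOX", "O3")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_field(grid, pair, rng, month="JAN", run_id="R1", scale=1.0):
    values = rng.normal(0.0, scale, size=grid.shape)
    return SensitivityField(grid, run_id, month, pair, values)
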