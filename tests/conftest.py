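import numpy as np
import pytest

from starchgran import (
    DiameterGrid,
    SizeDistribution,
    Weighting,
    expected_volume_density,
    make_preset,
)


@pytest.fixture(scope="session")
def wt_spec():
    return make_preset("WT_mature")


@pytest.fixture(scope="session")
def wt_expected(wt_spec):
    """Noiseless analytic volume density of the mature wild-type preset."""
    return expected_volume_density(wt_spec)


@pytest.fixture
def two_bin_grid():
    """Two bins whose geometric midpoints are exactly 1 and 2 μm."""
    return DiameterGrid(np.array([2**-0.5, 2**0.5, 2**1.5]))


def make_volume_dist(grid, values, **meta):
    values = np.asarray(values, dtype=float)
    return SizeDistribution(
        grid=grid,
        values=100.0 * values / values.sum(),
        weighting=Weighting.RELATIVE_VOLUME_PCT,
        normalized=True,
        **meta,
    )
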