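import numpy as np
import pytest

from tsgpbm import (
    ParticleSizeDistribution,
    build_geometric_grid,
    default_grid,
)


@pytest.fixture(scope="session")
def grid35():
    return default_grid()


@pytest.fixture(scope="session")
def grid6():
    return build_geometric_grid(6, 10.0, 1000.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def random_psd(grid, rng, scale=1e6):
    """Random strictly-positive PSD on a grid (test helper)."""
    return ParticleSizeDistribution(grid, scale * rng.random(grid.n_bins))
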