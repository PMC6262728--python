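import numpy as np
import pytest

from lynxlink.grids import Grid
from lynxlink.landscape import generate_landscape, generate_locations


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic landscape, shared across tests."""
    return generate_landscape(seed=42)


@pytest.fixture(scope="session")
def locations(bundle):
    return generate_locations(bundle)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_grid(values, cell_size=30.0, nodata=-9999.0):
    vals = np.asarray(values, dtype=float)
    return Grid(
        values=vals,
        cell_size=cell_size,
        origin_x=0.0,
        origin_y=vals.shape[0] * cell_size,
        nodata=nodata,
    )
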