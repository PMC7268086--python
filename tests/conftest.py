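import numpy as np
import pytest

from megfc.headmodel import build_source_grid, compute_lead_field
from megfc.rois import load_roi_table
from megfc.simulate import make_sensor_array


@pytest.fixture(scope="session")
def roi_table():
    return load_roi_table()


@pytest.fixture(scope="session")
def array():
    """Default 102-channel hemispheric magnetometer array."""
    return make_sensor_array(102, 0.12, 0.09)


@pytest.fixture(scope="session")
def grid(array):
    """Full 6-mm scanning grid for the default head."""
    return build_source_grid(array.head_radius, 6.0)


@pytest.fixture(scope="session")
def full_lead(grid, array):
    """Lead field over the full grid (built once per session)."""
    return compute_lead_field(grid, array)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
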