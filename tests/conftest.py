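import numpy as np
import pytest

from subnets.spaces import NodeSpace, Timeseries
from subnets.synthetic import PlantedDesign, grid_nodespace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_space():
    """5x5 grid, 6 mm spacing, 4-connected."""
    return grid_nodespace(25, spacing_mm=6.0)


@pytest.fixture
def medium_space():
    return grid_nodespace(400, spacing_mm=6.0)


@pytest.fixture
def small_design():
    return PlantedDesign(
        n_subjects=4,
        n_nodes=60,
        n_networks=2,
        subnetworks_per_network=2,
        rng_seed=42,
    )


@pytest.fixture
def noise_timeseries(rng):
    return Timeseries(subject_id="noise", values=rng.standard_normal((10, 500)), tr=1.0)
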