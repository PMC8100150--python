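import numpy as np
import pytest

from mpilocate import (AppliedFieldZ, build_lead_field, make_cuboid_bem,
                       make_sensor_plane)


@pytest.fixture(scope="session")
def coarse_grid():
    """6 x 6 x 5 cm cuboid at 0.5 cm spacing (13 x 13 x 11 nodes)."""
    return make_cuboid_bem([6.0, 6.0, 5.0], 0.5)


@pytest.fixture(scope="session")
def tiny_grid():
    """4 x 4 x 3 cm cuboid at 1 cm spacing (5 x 5 x 4 nodes, 100 voxels)."""
    return make_cuboid_bem([4.0, 4.0, 3.0], 1.0)


@pytest.fixture(scope="session")
def tiny_plane():
    """3 x 3 sensors, 1 cm above the tiny grid, centred on its footprint."""
    return make_sensor_plane([2.0, 2.0], 1.0, plane_z=4.0, center_xy=[2.0, 2.0])


@pytest.fixture(scope="session")
def tiny_lead_field(tiny_grid, tiny_plane):
    return build_lead_field(tiny_grid, tiny_plane,
                            AppliedFieldZ(gradient=0.0, bias=0.5))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210505)
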