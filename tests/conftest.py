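import numpy as np
import pytest

from cbctsc.phantom import (
    ApplicatorSpec,
    PhantomSpec,
    insert_applicator,
    make_pelvis_phantom,
)
from cbctsc.projector import ConeBeamGeometry, forward_project
from cbctsc.volume import make_centered_volume


@pytest.fixture(scope="session")
def small_phantom_spec():
    """Desk-size phantom: full anatomy at coarse resolution (fast tests)."""
    return PhantomSpec(grid_shape=(32, 96, 128), voxel_size=(4.5, 3.0, 3.0), seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    return make_pelvis_phantom(small_phantom_spec)


@pytest.fixture(scope="session")
def small_phantom_with_applicator(small_phantom):
    labels, hu = small_phantom
    return insert_applicator(labels, hu, ApplicatorSpec())


@pytest.fixture(scope="session")
def small_geometry():
    return ConeBeamGeometry(
        detector_pixels=(128, 64),
        pixel_pitch=4.8,
        view_angles_deg=np.arange(0.0, 360.0, 3.0),
    )


@pytest.fixture(scope="session")
def cylinder_volume():
    """Uniform water-like cylinder, mu = 0.02/mm, radius 50 mm, height 80 mm."""
    vol = make_centered_volume((48, 96, 96), (2.0, 2.0, 2.0), unit="1/mm")
    z, y, x = vol.world_grid()
    inside = ((y**2 + x**2) <= 50.0**2) & (np.abs(z) <= 40.0)
    vol.data[np.broadcast_to(inside, vol.shape)] = 0.02
    return vol


@pytest.fixture(scope="session")
def cylinder_geometry():
    return ConeBeamGeometry(
        detector_pixels=(192, 96),
        pixel_pitch=1.552,
        view_angles_deg=np.arange(0.0, 360.0, 2.0),
    )


@pytest.fixture(scope="session")
def cylinder_projections(cylinder_volume, cylinder_geometry):
    return forward_project(cylinder_volume, cylinder_geometry)
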