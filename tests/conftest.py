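import numpy as np
import pytest

from cryomargin.imaging_io import BinaryMask, ImageGeometry
from cryomargin.synthetic_data import Ellipsoid, PhantomSpec, make_phantom


def build_mask(voxels, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> BinaryMask:
    voxels = np.asarray(voxels, dtype=np.uint8)
    geom = ImageGeometry.from_spacing(voxels.shape, spacing, origin)
    return BinaryMask(geom, voxels)


def sphere_phantom(r_tumor, r_ice, offset=(0.0, 0.0, 0.0), shape=(64, 64, 64),
                   spacing=(1.0, 1.0, 1.0)):
    """Sphere pair centered in the grid, ice displaced by ``offset`` mm."""
    center = tuple(0.5 * (np.asarray(shape) - 1) * np.asarray(spacing))
    ice_center = tuple(np.asarray(center) + np.asarray(offset))
    spec = PhantomSpec(
        shape=shape, spacing=spacing,
        tumor=Ellipsoid(center, (r_tumor,) * 3),
        ice=Ellipsoid(ice_center, (r_ice,) * 3),
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def concentric_10_15():
    """Tumor r=10 mm inside ice r=15 mm, 1 mm isotropic: analytic MTM +5."""
    return sphere_phantom(10.0, 15.0)
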