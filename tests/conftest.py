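import numpy as np
import pytest

from cubemag.geometry import DiscretizedGeometry, build_truncated_cube
from cubemag.materials import magnetite


@pytest.fixture(scope="session")
def mat():
    return magnetite()


@pytest.fixture(scope="session")
def cube20(mat):
    """The l = 20 nm truncated cube at the default 1.25 nm cell size."""
    return build_truncated_cube(20.0, 1.25)


@pytest.fixture()
def macrospin_geom():
    """Single-cell particle (macrospin limit)."""
    mask = np.ones((1, 1, 1), bool)
    return DiscretizedGeometry(ds=5.0, mask=mask, origin=np.zeros(3),
                               particle_id=np.zeros((1, 1, 1), int))


def macrospin(ds=5.0):
    mask = np.ones((1, 1, 1), bool)
    return DiscretizedGeometry(ds=ds, mask=mask, origin=np.zeros(3),
                               particle_id=np.zeros((1, 1, 1), int))
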