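import numpy as np
import pytest

from cardioib.geometry import LVGeometryParams, make_idealized_lv, build_fiber_field
from cardioib.materials import FiberFrame


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140701)


@pytest.fixture(scope="session")
def lv_mesh():
    """Default-preset idealized LV mesh (session-wide, read-only)."""
    return make_idealized_lv(LVGeometryParams())


@pytest.fixture(scope="session")
def coarse_mesh():
    """Small mesh for force-assembly and quadrature tests."""
    return make_idealized_lv(LVGeometryParams(r_endo=1.1, wall=0.9, length=2.8,
                                              truncation=0.6, edge_length=0.9))


@pytest.fixture(scope="session")
def lv_fibers(lv_mesh):
    return build_fiber_field(lv_mesh)


def random_deformation(rng, n=None, spread=0.2, det_range=None):
    """Random deformation gradients with positive determinant."""
    shape = (3, 3) if n is None else (n, 3, 3)
    while True:
        F = np.eye(3) + spread * rng.normal(size=shape)
        J = np.linalg.det(F)
        if np.all(J > 0.05):
            if det_range is None:
                return F
            lo, hi = det_range
            # rescale determinants into the requested band
            target = rng.uniform(lo, hi, size=np.shape(J))
            F = F * np.cbrt(target / J)[..., None, None]
            return F


def random_frame(rng):
    f0 = rng.normal(size=3)
    s0 = rng.normal(size=3)
    return FiberFrame.from_vectors(f0, s0)
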