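import numpy as np
import pytest

from annpet.geometry import ScannerGeometry
from annpet.optics import OpticalModel, NoiseConfig


@pytest.fixture(scope="session")
def geom():
    return ScannerGeometry()


@pytest.fixture(scope="session")
def optical_model():
    return OpticalModel()


@pytest.fixture(scope="session")
def noise_cfg():
    return NoiseConfig()


@pytest.fixture(scope="session")
def uniform_pe_points(geom):
    """Uniform interaction points over facet area and depth (seeded)."""
    rng = np.random.default_rng(20240915)
    n = 3000
    a = geom.annulus
    u = rng.uniform(-a.facet_width / 2, a.facet_width / 2, n)
    z = rng.uniform(-a.length / 2 + 2, a.length / 2 - 2, n)
    lo = np.sqrt(np.maximum(a.inner_radius**2 - u**2, 0.0))
    nc = rng.uniform(lo, a.facet_apothem, n)
    facet = rng.integers(0, geom.n_facets, n)
    pts = (geom.origins[facet] + u[:, None] * geom.u_axes[facet]
           + (nc - a.facet_apothem)[:, None] * geom.normals[facet])
    pts[:, 2] = z
    return pts[geom.contains(pts)]
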