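import numpy as np
import pytest

import dtsmem as d


@pytest.fixture(scope="session")
def icosphere2():
    return d.build_icosphere(2)


@pytest.fixture(scope="session")
def icosphere3():
    return d.build_icosphere(3)


@pytest.fixture(scope="session")
def flat88():
    return d.build_flat_grid(8, 8, 1.2)


@pytest.fixture(scope="session")
def tube1616():
    return d.build_tube(16, 16)


@pytest.fixture(scope="session")
def torus_fine():
    return d.build_torus(60, 20, 10.0, 3.2)


@pytest.fixture(scope="session")
def geom_sphere3(icosphere3):
    return d.SurfaceGeometry(icosphere3)


@pytest.fixture(scope="session")
def geom_flat(flat88):
    return d.SurfaceGeometry(flat88)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def sphere_radius(mesh):
    c = mesh.pos.mean(axis=0)
    return float(np.linalg.norm(mesh.pos - c, axis=1).mean())
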