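import numpy as np
import pytest

from cryonet import params as P


@pytest.fixture(scope="session")
def wp():
    return P.FreeVolumeWaterParams()


@pytest.fixture(scope="session")
def cpa():
    return P.FreeVolumeCPAParams()


@pytest.fixture(scope="session")
def rp():
    return P.RegionProperties()


@pytest.fixture(scope="session")
def mp():
    return P.MembraneParams()


@pytest.fixture(scope="session")
def nucl():
    return P.NucleationParams()


@pytest.fixture(scope="session")
def geom():
    return P.CellGeometry()


@pytest.fixture()
def sphere_state(rp, mp):
    """Spherical cell (no nucleus) loaded with the default solution."""
    from cryonet.transport import build_mesh

    g = P.CellGeometry(l_maj=20.0, l_min=20.0, has_nucleus=False)
    return build_mesh(g, (12, 12), rp, mp, 4.8, 0.142)


@pytest.fixture()
def oocyte_state(geom, rp, mp):
    from cryonet.transport import build_mesh

    return build_mesh(geom, (16, 16), rp, mp, 4.8, 0.142)
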