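import numpy as np
import pytest

from dpdgel.params import BondedParams, DPDParams, NetworkParams
from dpdgel.system import BeadSystem


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def dpd():
    return DPDParams()


@pytest.fixture
def bonded():
    return BondedParams()


def make_fluid_box(n=500, L=6.0, kBT=1.0, seed=0, pbc_z=True):
    rng = np.random.default_rng(seed)
    pos = rng.random((n, 3)) * L
    sys_ = BeadSystem(pos, np.zeros((n, 3)), np.zeros(n, np.int8),
                      (L, L, L), pbc_z=pbc_z)
    if kBT > 0:
        sys_.thermalize(kBT, rng)
    return sys_


@pytest.fixture(scope="session")
def small_network():
    """A small built gel network shared across tests (read-only)."""
    from dpdgel.builder import build_gel

    params = NetworkParams(box=(12.0, 12.0, 12.0), seed=3)
    system, topo, report = build_gel(params)
    return params, system, topo, report
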