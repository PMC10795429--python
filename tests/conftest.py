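import numpy as np
import pytest

from protonmc import materials as M
from protonmc import nuclear as N
from protonmc.transport import TransportConfig, TransportKernelData


@pytest.fixture(scope="session")
def registry():
    return M.build_default_registry()


@pytest.fixture(scope="session")
def tables():
    return M.build_default_tables()


@pytest.fixture(scope="session")
def nucdb(tables):
    return N.generate_default_db(tables.elements)


@pytest.fixture(scope="session")
def kdata(tables, nucdb):
    """Kernel data with all physics enabled."""
    return TransportKernelData(tables, nucdb, TransportConfig())


@pytest.fixture(scope="session")
def material_ids(tables):
    return {m.name: m.id for m in tables.materials}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
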