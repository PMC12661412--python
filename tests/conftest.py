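import numpy as np
import pytest

from idkit import IDDatabase
from idkit.phantom import synthetic_ip_curves


@pytest.fixture(scope="session")
def curves3():
    """Synthetic F_k(E) curve sets for three representative species."""
    return synthetic_ip_curves(("proton", "C", "O"))


@pytest.fixture(scope="session")
def synthetic_db(curves3):
    """Database tabulated from the synthetic curves on 5% adaptive grids."""
    return IDDatabase.from_curves(curves3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
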