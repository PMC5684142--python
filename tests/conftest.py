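import numpy as np
import pytest

from poolsim import ResourceEnvironment, SpeciesPool
from poolsim.config import make_fixture_pool


@pytest.fixture(scope="session")
def fixture_pool() -> SpeciesPool:
    """Deterministic 8-species triple-trade-off pool."""
    return make_fixture_pool()


@pytest.fixture
def env() -> ResourceEnvironment:
    """A mid-gradient resource level."""
    return ResourceEnvironment(a=0.85, S=1.1)


@pytest.fixture
def single_species_pool() -> SpeciesPool:
    """The worked single-species example (R* = 0.8)."""
    return SpeciesPool(f=np.array([1.6]), m=np.array([1.28]),
                       l=np.array([2.05]), c=0.6)
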