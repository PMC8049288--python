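import numpy as np
import pytest

from delaycomm import netsim


@pytest.fixture(scope="session")
def default_net():
    """Single default population, frozen connectivity."""
    return netsim.build_network(netsim.PopulationSpec(), seed=0)


@pytest.fixture(scope="session")
def default_raster(default_net):
    """1.2 s of the default population (enough for 20+ cycles past the
    500 ms transient); shared across measurement tests."""
    return netsim.simulate(default_net, 1200.0, seed=1)
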