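import numpy as np
import pytest

from critsync import network as nw
from critsync.dynamics import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def net625():
    """Deterministic 625-node base assembly (no rich club, untyped)."""
    return nw.assemble_replicas(nw.build_base_network(2))


@pytest.fixture(scope="session")
def typed625():
    """625-node network, case 1, kappa=0.5, eta=0, fixed seed."""
    r = np.random.default_rng(777)
    net = nw.assemble_replicas(nw.build_base_network(2))
    net = nw.connect_rich_club(net, 0.5, r)
    return nw.assign_neuron_types(net, case=1, eta=0.0, rng=r)


@pytest.fixture
def short_config():
    """Reduced-length simulation for unit tests."""
    return SimulationConfig(transient_steps=500, record_steps=1500)
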