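import numpy as np
import pytest

from rchp import (
    NetworkParams,
    PlasticityParams,
    PlasticityState,
    build_network,
)


@pytest.fixture
def small_params():
    """A reduced substrate for fast unit tests (same physics, fewer neurons)."""
    return NetworkParams(n_excitatory=200, n_inhibitory=50, group_size=20)


@pytest.fixture
def small_net(small_params):
    rng = np.random.default_rng(42)
    net = build_network(
        small_params, [("S1", "input"), ("A0", "output")], rng
    )
    return net, rng


@pytest.fixture
def small_plastic(small_net):
    net, rng = small_net
    plast = PlasticityState.create(
        PlasticityParams(), net.n_synapses, net.params.dt
    )
    return net, plast, rng
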