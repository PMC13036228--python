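import numpy as np
import pytest

from afterimage import nef_core as nef


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def run_scalar_network(value, neuron_params, polarity, npp, mode, seed=0, duration=0.5,
                       probe_tau=0.02, radius=1.0):
    """Encode a constant scalar in one ensemble and return the probe trace."""
    net = nef.Network()
    inp = net.add_node(np.atleast_1d(value), 1, "in")
    ens = net.add_ensemble(1, neuron_params, polarity=polarity, neurons_per_dim=npp,
                           radius=radius, label="x")
    net.connect(inp, ens, synapse=nef.Lowpass(0.005))
    probe = net.probe(ens, synapse=nef.Lowpass(probe_tau) if probe_tau else None)
    sim = nef.Simulator(net, seed=seed, mode=mode)
    return sim.run(duration)[probe]
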