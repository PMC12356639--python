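import numpy as np
import pytest

from spwnet.neuron import NeuronParams, CELL_PARAMS
from spwnet.network import (PopulationSpec, ConnectivitySpec, SynapseSpec,
                            build_network)


@pytest.fixture(scope="session")
def small_pops():
    """Scaled-down populations (same neuron parameters) for fast engine tests."""
    sizes = {"A": 60, "T": 120, "B": 20, "C": 15}
    return tuple(PopulationSpec(n, sizes[n], CELL_PARAMS[n]) for n in "ATBC")


@pytest.fixture(scope="session")
def small_net(small_pops):
    return build_network(pops=small_pops, seed=7)


def two_neuron_net(w_ta: float = 0.5, i_pre: float = 400.0,
                   i_post: float = 0.0, **kwargs):
    """One athorny cell driving one thorny cell (block T<-A only)."""
    pops = (
        PopulationSpec("A", 1, CELL_PARAMS["A"].with_(I_ext=i_pre)),
        PopulationSpec("T", 1, CELL_PARAMS["T"].with_(I_ext=i_post)),
        PopulationSpec("B", 0, CELL_PARAMS["B"]),
        PopulationSpec("C", 0, CELL_PARAMS["C"]),
    )
    p = np.zeros((4, 4))
    p[1, 0] = 1.0
    w = SynapseSpec().w.copy()
    w[1, 0] = w_ta
    return build_network(pops=pops, conn=ConnectivitySpec(p=p),
                         syn=SynapseSpec(w=w), seed=0, **kwargs)
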