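import numpy as np
import pytest

from whalesong.demography import PopulationDemography
from whalesong.model_core import LearningParams
from whalesong.simulator import SimulationConfig, Topology


@pytest.fixture
def tiny_ring():
    """Three small populations on a ring, mild growth."""
    labels = ("A", "B", "C")
    topo = Topology.ring(labels)
    demog = tuple(PopulationDemography(l, 12, 40, 90, 50) for l in labels)
    return topo, demog


@pytest.fixture
def tiny_config(tiny_ring):
    topo, demog = tiny_ring
    params = LearningParams(
        N_t=4, P_n=0.05, mu=1e-4, L_sm=8, P_d=4.0, P_i=2.0
    )
    return SimulationConfig(
        topology=topo, demography=demog, params=params,
        years=14, seed=11, sample_size=8,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
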