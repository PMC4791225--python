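import numpy as np
import pytest

from itrkit import synthetic_data as synth
from itrkit.knowledge_io import PriorEdge, build_prior_network
from itrkit.omics_contrasts import EvidenceSet


@pytest.fixture
def tiny_network():
    """Two regulators: R1 activates A and B, R2 activates C."""
    return build_prior_network(
        [
            PriorEdge("R1", "A", sign="activates"),
            PriorEdge("R1", "B", sign="activates"),
            PriorEdge("R2", "C", sign="activates"),
        ]
    )


@pytest.fixture
def tiny_evidence():
    return EvidenceSet(
        condition="toy",
        genes={"A", "B"},
        universe={"A", "B", "C", "D"},
        directions={"A": 1, "B": 1},
    )


@pytest.fixture(scope="session")
def default_scenario():
    return synth.default_scenario(seed=11)


@pytest.fixture(scope="session")
def scenario_outputs(default_scenario):
    """Network, contrasts and truth for the default scenario (built once)."""
    network = synth.generate_prior_network(default_scenario)
    tables, truth = synth.generate_contrasts(network, default_scenario)
    return network, tables, truth


@pytest.fixture
def rng():
    return np.random.default_rng(7)
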