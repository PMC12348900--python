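import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from actd_cbm.core import MetabolicNetwork, Reaction, Species  # noqa: E402
from actd_cbm.synth import ToyWorldConfig, make_toy_world  # noqa: E402


@pytest.fixture(scope="session")
def toy_world():
    """The default seeded toy world shared across tests."""
    return make_toy_world(ToyWorldConfig(seed=1))


@pytest.fixture(scope="session")
def toy_world_protein_free():
    return make_toy_world(ToyWorldConfig(seed=2, include_protein_module=False))


@pytest.fixture()
def chain_network():
    """EX -> A -> biomass with uptake cap 10 and unit yield."""
    species = [Species(id="a_c", compartment="c")]
    reactions = [
        Reaction(id="EX_a", stoichiometry={"a_c": -1.0}, ub_b=10.0, is_exchange=True),
        Reaction(id="GROW", stoichiometry={"a_c": -1.0}, ub_f=1000.0),
    ]
    net = MetabolicNetwork(species, reactions, id="chain")
    net.objectives.biomass = "GROW"
    return net


@pytest.fixture()
def two_path_network():
    """A source species routed to a drain either through a two-step
    high-confidence path or a one-step unsupported path."""
    species = [Species(id=s, compartment="c") for s in ("a_c", "x_c", "b_c")]
    reactions = [
        Reaction(id="EX_a", stoichiometry={"a_c": -1.0}, ub_b=10.0, is_exchange=True),
        Reaction(id="LONG1", stoichiometry={"a_c": -1.0, "x_c": 1.0}),
        Reaction(id="LONG2", stoichiometry={"x_c": -1.0, "b_c": 1.0}),
        Reaction(id="SHORT", stoichiometry={"a_c": -1.0, "b_c": 1.0}),
        Reaction(id="DRAIN", stoichiometry={"b_c": -1.0}),
    ]
    net = MetabolicNetwork(species, reactions, id="two_path")
    net.objectives.biomass = "DRAIN"
    return net
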