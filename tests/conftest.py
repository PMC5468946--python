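import pytest

from adipoflux import (
    GPRRule,
    Metabolite,
    MetabolicNetwork,
    ObjectiveDefinition,
    Reaction,
    SyntheticSpec,
    generate_network,
)


def make_chain_network(r1_upper=1000.0, uptake=10.0):
    """EX_A (uptake) → R1: A→B → DM_B with objective on the drain."""
    return MetabolicNetwork(
        metabolites=[Metabolite(id="A", compartment="c"), Metabolite(id="B", compartment="c")],
        reactions=[
            Reaction("EX_A", {"A": -1.0}, -uptake, 1000.0),
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, r1_upper,
                     gpr=GPRRule.from_sets([{"g1"}])),
            Reaction("DM_B", {"B": -1.0}, 0.0, 1000.0),
        ],
        genes=["g1"],
        objectives={"drain": ObjectiveDefinition("drain", {"DM_B": 1.0})},
        id="chain",
    )


def make_parallel_network(uptake=10.0):
    """A→B through two interchangeable routes gated by different genes."""
    return MetabolicNetwork(
        metabolites=[Metabolite(id="A", compartment="c"), Metabolite(id="B", compartment="c")],
        reactions=[
            Reaction("EX_A", {"A": -1.0}, -uptake, 1000.0),
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0,
                     gpr=GPRRule.from_sets([{"g1"}])),
            Reaction("R2", {"A": -1.0, "B": 1.0}, 0.0, 1000.0,
                     gpr=GPRRule.from_sets([{"g2"}])),
            Reaction("DM_B", {"B": -1.0}, 0.0, 1000.0),
        ],
        genes=["g1", "g2"],
        objectives={"drain": ObjectiveDefinition("drain", {"DM_B": 1.0})},
        id="parallel",
    )


@pytest.fixture
def chain_network():
    return make_chain_network()


@pytest.fixture
def parallel_network():
    return make_parallel_network()


@pytest.fixture(scope="session")
def synthetic_net_truth():
    return generate_network(SyntheticSpec(seed=1))
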