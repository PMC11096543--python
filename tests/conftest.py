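import pytest

from polyflux.network import MetabolicNetwork, Metabolite, Reaction
from polyflux.rates import estimate_sample_rates
from polyflux.synthetic import default_scenario, simulate_experiment
from polyflux.tcell_core import core_tcell_network


def _met(mid, boundary=False):
    return Metabolite(id=mid, compartment="extracellular" if boundary else "cytosol",
                      is_boundary=boundary)


def make_chain_network(uptake=(-1.0, -1.0)):
    """A_b -> A -> B -> C -> C_b with the uptake flux clamped to a window."""
    return MetabolicNetwork(
        metabolites=[_met("A"), _met("B"), _met("C"),
                     _met("A_b", boundary=True), _met("C_b", boundary=True)],
        reactions=[
            Reaction("EX_A", {"A": -1, "A_b": 1}, uptake[0], uptake[1],
                     is_exchange=True),
            Reaction("R1", {"A": -1, "B": 1}, 0, 10),
            Reaction("R2", {"B": -1, "C": 1}, 0, 10),
            Reaction("EX_C", {"C": -1, "C_b": 1}, 0, 10, is_exchange=True),
        ],
        biomass_reaction_id="R2",
        compartments=["cytosol", "extracellular"],
    )


def make_parallel_network():
    """Unit input split over two parallel branches A -> B."""
    return MetabolicNetwork(
        metabolites=[_met("A"), _met("B"),
                     _met("A_b", boundary=True), _met("B_b", boundary=True)],
        reactions=[
            Reaction("EX_A", {"A": -1, "A_b": 1}, -1.0, -1.0, is_exchange=True),
            Reaction("BR1", {"A": -1, "B": 1}, 0, 10),
            Reaction("BR2", {"A": -1, "B": 1}, 0, 10),
            Reaction("EX_B", {"B": -1, "B_b": 1}, 0, 10, is_exchange=True),
        ],
        biomass_reaction_id="BR1",
        compartments=["cytosol", "extracellular"],
    )


def make_cycle_network():
    """Chain A->B plus an independent reversible 3-cycle X->Y->Z->X.

    The cycle is a pure internal circulation: any nonzero coherent flux
    around it satisfies mass balance but violates the loop law.
    """
    return MetabolicNetwork(
        metabolites=[_met("A"), _met("B"), _met("X"), _met("Y"), _met("Z"),
                     _met("A_b", boundary=True), _met("B_b", boundary=True)],
        reactions=[
            Reaction("EX_A", {"A": -1, "A_b": 1}, -1.0, -1.0, is_exchange=True),
            Reaction("R1", {"A": -1, "B": 1}, 0, 10),
            Reaction("EX_B", {"B": -1, "B_b": 1}, 0, 10, is_exchange=True),
            Reaction("C1", {"X": -1, "Y": 1}, -10, 10),
            Reaction("C2", {"Y": -1, "Z": 1}, -10, 10),
            Reaction("C3", {"Z": -1, "X": 1}, -10, 10),
        ],
        biomass_reaction_id="R1",
        compartments=["cytosol", "extracellular"],
    )


@pytest.fixture(scope="session")
def core_net():
    return core_tcell_network()


@pytest.fixture
def chain_net():
    return make_chain_network()


@pytest.fixture
def parallel_net():
    return make_parallel_network()


@pytest.fixture
def cycle_net():
    return make_cycle_network()


@pytest.fixture(scope="session")
def noiseless_scenario():
    """Zero-noise synthetic condition on the core network (shared: expensive)."""
    return default_scenario(seed=3, conc_noise_sd=0.0, count_noise_sd=0.0,
                            expr_noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_measurements(noiseless_scenario):
    """(mu_hat, ExchangeRateSet) of the first simulated mouse, zero noise."""
    exp = simulate_experiment(noiseless_scenario)
    g = exp.growth[0]
    mu, rs = estimate_sample_rates(g, exp.supernatant[g.sample_id])
    return mu, rs
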