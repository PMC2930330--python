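import numpy as np
import pytest

from panfba import (
    CoreNetworkParams,
    Metabolite,
    MetabolicModel,
    Reaction,
    generate_core_network,
    minimal_medium,
)


@pytest.fixture(scope="session")
def default_network():
    return generate_core_network()


@pytest.fixture(scope="session")
def default_medium():
    return minimal_medium()


@pytest.fixture()
def toy_chain_model():
    """uptake -> convert -> biomass chain, 1:1 stoichiometry, uptake cap 5."""
    m = MetabolicModel("toy")
    m.add_metabolite(Metabolite("s_e", compartment="e", formula="C1"))
    m.add_metabolite(Metabolite("s_c", compartment="c", formula="C1"))
    m.add_metabolite(Metabolite("x_c", compartment="c", formula="C1"))
    m.add_reaction(Reaction("EX_s_e", {"s_e": -1.0}, lb=-5.0, ub=1000.0, kind="exchange"))
    m.add_reaction(Reaction("T", {"s_e": -1.0, "s_c": 1.0}, lb=0.0, ub=1000.0))
    m.add_reaction(Reaction("CONV", {"s_c": -1.0, "x_c": 1.0}, lb=0.0, ub=1000.0))
    m.add_reaction(Reaction("BIO", {"x_c": -1.0}, lb=0.0, ub=1000.0, kind="demand"))
    m.objective_rxn_id = "BIO"
    return m


def random_lp_network(rng: np.random.Generator, max_rxns: int = 8):
    """A random small metabolic LP with finite bounds containing zero.

    Feasibility is guaranteed (v = 0 is feasible) and boundedness follows
    from the finite box, so the LP optimum is attained at a vertex and a
    brute-force vertex enumeration is a valid oracle.
    """
    n_rxns = int(rng.integers(2, max_rxns + 1))
    n_mets = int(rng.integers(1, max(2, n_rxns - 1)))
    m = MetabolicModel("rand")
    for i in range(n_mets):
        m.add_metabolite(Metabolite(f"m{i}", compartment="c"))
    for j in range(n_rxns):
        stoich = {}
        for i in range(n_mets):
            if rng.random() < 0.6:
                coeff = float(rng.integers(-3, 4))
                if coeff:
                    stoich[f"m{i}"] = coeff
        if not stoich:
            stoich[f"m{int(rng.integers(0, n_mets))}"] = 1.0
        lb = float(rng.uniform(-10, 0))
        ub = float(rng.uniform(0, 10))
        m.add_reaction(Reaction(f"r{j}", stoich, lb=lb, ub=ub))
    m.objective_rxn_id = f"r{int(rng.integers(0, n_rxns))}"
    return m
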