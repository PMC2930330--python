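import numpy as np
import pytest

from panfba import (
    Metabolite,
    MetabolicModel,
    Reaction,
    carbon_fractions,
    flux_variability,
    knockout,
    robustness_scan,
    solve_fba,
)
from panfba.fba import FluxSolution

from .conftest import random_lp_network
from .oracles import carbon_fractions_power_iteration, vertex_enumeration_optimum


class TestSolveFBA:
    def test_three_reaction_chain_hits_the_uptake_cap(self, toy_chain_model):
        sol = solve_fba(toy_chain_model)
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(5.0)

    def test_closed_medium_gives_zero_growth(self):
        from panfba import CoreNetworkParams, generate_core_network

        # without the maintenance floor, a closed medium means zero growth
        model = generate_core_network(CoreNetworkParams(ngam=0.0))
        sol = solve_fba(model, medium={})
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_default_network_grows_at_the_calibrated_rate(
        self, default_network, default_medium
    ):
        sol = solve_fba(default_network, medium=default_medium)
        assert sol.objective == pytest.approx(0.014, abs=1e-4)

    def test_optimum_matches_vertex_enumeration_on_random_networks(self):
        rng = np.random.default_rng(1234)
        checked = 0
        for _ in range(40):
            model = random_lp_network(rng)
            sol = solve_fba(model)
            oracle = vertex_enumeration_optimum(model)
            assert sol.status == "optimal"
            assert oracle is not None
            assert sol.objective == pytest.approx(oracle, abs=1e-6)
            checked += 1
        assert checked == 40

    def test_bounds_and_steady_state_hold_at_the_optimum(
        self, default_network, default_medium
    ):
        from panfba.model import apply_medium, stoichiometric_matrix

        constrained = apply_medium(default_network, default_medium)
        sol = solve_fba(constrained)
        S, _m, rxns = stoichiometric_matrix(constrained)
        v = np.array([sol.fluxes[r] for r in rxns])
        assert np.max(np.abs(S @ v)) < 1e-6
        for rxn in constrained.reactions.values():
            assert rxn.lb - 1e-9 <= sol.fluxes[rxn.rxn_id] <= rxn.ub + 1e-9

    def test_objective_invariant_under_metabolite_row_scaling(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            model = random_lp_network(rng)
            base = solve_fba(model).objective
            scaled = model.copy()
            factors = {m: float(rng.uniform(0.1, 10)) for m in scaled.metabolites}
            for rxn in scaled.reactions.values():
                rxn.stoich = {m: c * factors[m] for m, c in rxn.stoich.items()}
            assert solve_fba(scaled).objective == pytest.approx(base, abs=1e-7)

    def test_relaxing_any_bound_never_decreases_the_objective(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            model = random_lp_network(rng)
            base = solve_fba(model).objective
            relaxed = model.copy()
            rxn_id = list(relaxed.reactions)[int(rng.integers(0, len(relaxed.reactions)))]
            relaxed.reactions[rxn_id].lb -= float(rng.uniform(0, 5))
            relaxed.reactions[rxn_id].ub += float(rng.uniform(0, 5))
            assert solve_fba(relaxed).objective >= base - 1e-7

    def test_infeasible_problem_reports_status_not_zeros(self):
        m = MetabolicModel("bad")
        m.add_metabolite(Metabolite("a"))
        # production forced, no consumption possible
        m.add_reaction(Reaction("make", {"a": 1.0}, lb=1.0, ub=2.0))
        m.objective_rxn_id = "make"
        sol = solve_fba(m)
        assert sol.status == "infeasible"
        assert not sol.optimal


class TestKnockout:
    def test_gene_outside_all_gprs_changes_nothing(
        self, default_network, default_medium
    ):
        from panfba.model import Gene

        model = default_network.copy()
        model.add_gene(Gene("orphan_gene"))
        base = solve_fba(model, medium=default_medium).objective
        sol = knockout(model, {"orphan_gene"}, medium=default_medium)
        assert sol.objective == pytest.approx(base, rel=1e-9)

    def test_pyruvate_synthase_is_essential(self, default_network, default_medium):
        # POR is the only route from acetyl-CoA to pyruvate
        sol = knockout(default_network, {"porA"}, medium=default_medium)
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_isozyme_pair_requires_a_double_knockout(
        self, default_network, default_medium
    ):
        base = solve_fba(default_network, medium=default_medium).objective
        single = knockout(default_network, {"acs1"}, medium=default_medium)
        assert single.objective == pytest.approx(base, rel=1e-6)
        double = knockout(default_network, {"acs1", "acs2"}, medium=default_medium)
        assert double.objective == pytest.approx(0.0, abs=1e-9)

    def test_unknown_gene_raises(self, default_network, default_medium):
        with pytest.raises(KeyError):
            knockout(default_network, {"no_such_gene"}, medium=default_medium)


class TestRobustnessScan:
    def test_objective_monotone_in_uptake_allowance(
        self, default_network, default_medium
    ):
        curve = robustness_scan(
            default_network, default_medium, "EX_h2_e", np.linspace(0, 20, 11)
        )
        assert curve.objective[0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(np.diff(curve.objective) >= -1e-9)

    def test_zero_allowance_of_essential_nutrient_kills_growth(
        self, default_network, default_medium
    ):
        curve = robustness_scan(
            default_network, default_medium, "EX_cbl1_e", [0.0, 1e-5]
        )
        assert curve.objective[0] == pytest.approx(0.0, abs=1e-9)
        assert curve.objective[1] > 0

    def test_cobalamin_breakpoint_matches_closed_form(
        self, default_network, default_medium
    ):
        # growth plateaus once salvage exceeds mu_max * biomass coefficient
        bio = default_network.objective
        coeff = -bio.stoich["cbl1_c"]
        mu_max = solve_fba(default_network, medium=default_medium).objective
        breakpoint = mu_max * coeff
        curve = robustness_scan(
            default_network, default_medium, "EX_cbl1_e",
            [0.5 * breakpoint, 0.99 * breakpoint, 1.01 * breakpoint, 2 * breakpoint],
        )
        assert curve.objective[1] < mu_max * 0.999
        assert curve.objective[2] == pytest.approx(mu_max, rel=1e-2)
        assert curve.objective[3] == pytest.approx(mu_max, rel=1e-6)


class TestCarbonFractions:
    def test_single_carbon_source_gets_everything(self, toy_chain_model):
        sol = solve_fba(toy_chain_model)
        fractions = carbon_fractions(sol, toy_chain_model)
        assert fractions == {"EX_s_e": pytest.approx(1.0)}

    def test_core_network_splits_one_third_co2_two_thirds_acetate(
        self, default_network, default_medium
    ):
        sol = solve_fba(default_network, medium=default_medium)
        fractions = carbon_fractions(sol, default_network)
        assert fractions["EX_co2_e"] == pytest.approx(1 / 3, abs=5e-4)
        assert fractions["EX_ac_e"] == pytest.approx(2 / 3, abs=5e-4)
        # the chlorinated electron acceptor is pass-through carbon
        assert fractions.get("EX_pce_e", 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_matches_power_iteration_oracle_on_the_core_network(
        self, default_network, default_medium
    ):
        sol = solve_fba(default_network, medium=default_medium)
        mine = carbon_fractions(sol, default_network)
        brute = carbon_fractions_power_iteration(sol, default_network)
        assert set(mine) == set(brute)
        for ex, val in mine.items():
            assert val == pytest.approx(brute[ex], abs=1e-8)

    def test_matches_oracle_on_a_branched_toy(self):
        # two sources feeding one biomass precursor through a mixing node
        m = MetabolicModel("toy2")
        for met, comp, formula in [
            ("a_e", "e", "C2"), ("b_e", "e", "C1"), ("a_c", "c", "C2"),
            ("b_c", "c", "C1"), ("x_c", "c", "C3"),
        ]:
            m.add_metabolite(Metabolite(met, compartment=comp, formula=formula))
        m.add_reaction(Reaction("EX_a_e", {"a_e": -1}, lb=-4, kind="exchange"))
        m.add_reaction(Reaction("EX_b_e", {"b_e": -1}, lb=-10, kind="exchange"))
        m.add_reaction(Reaction("Ta", {"a_e": -1, "a_c": 1}))
        m.add_reaction(Reaction("Tb", {"b_e": -1, "b_c": 1}))
        m.add_reaction(Reaction("MIX", {"a_c": -1, "b_c": -1, "x_c": 1}))
        m.add_reaction(Reaction("BIO", {"x_c": -1}, kind="demand"))
        m.objective_rxn_id = "BIO"
        sol = solve_fba(m)
        mine = carbon_fractions(sol, m)
        brute = carbon_fractions_power_iteration(sol, m)
        assert mine["EX_a_e"] == pytest.approx(2 / 3)
        assert mine["EX_b_e"] == pytest.approx(1 / 3)
        for ex in mine:
            assert mine[ex] == pytest.approx(brute[ex], abs=1e-8)

    def test_missing_formula_on_a_carbon_exchange_raises(self):
        from panfba.model import FormulaError

        m = MetabolicModel("t")
        m.add_metabolite(Metabolite("a_e", compartment="e"))  # no formula
        m.add_reaction(Reaction("EX_a_e", {"a_e": -1}, lb=-5, kind="exchange"))
        m.add_reaction(Reaction("BIO", {"a_e": -1}, kind="demand"))
        m.objective_rxn_id = "BIO"
        sol = solve_fba(m)
        with pytest.raises(FormulaError):
            carbon_fractions(sol, m)


class TestFluxVariability:
    def test_single_path_fluxes_are_certified_unique(self, toy_chain_model):
        fva = flux_variability(toy_chain_model)
        for rxn_id, (lo, hi) in fva.items():
            assert hi - lo < 1e-6, rxn_id
            assert abs(hi) == pytest.approx(5.0, abs=1e-6)


class TestCobraCrossCheck:
    def test_objective_agrees_with_cobrapy_on_the_core_network(
        self, default_network, default_medium
    ):
        """Independent solver route: the same network assembled in COBRApy
        (GLPK) must reach the same optimum as the in-package HiGHS LP."""
        cobra = pytest.importorskip("cobra")
        from panfba.model import apply_medium

        constrained = apply_medium(default_network, default_medium)
        cm = cobra.Model("xcheck")
        cobra_mets = {
            met.met_id: cobra.Metabolite(met.met_id, compartment=met.compartment)
            for met in constrained.metabolites.values()
        }
        for rxn in constrained.reactions.values():
            cr = cobra.Reaction(rxn.rxn_id, lower_bound=rxn.lb, upper_bound=rxn.ub)
            cm.add_reactions([cr])
            cr.add_metabolites(
                {cobra_mets[m]: c for m, c in rxn.stoich.items()}
            )
        cm.objective = constrained.objective_rxn_id
        mu_cobra = cm.optimize().objective_value
        mu_mine = solve_fba(constrained).objective
        assert mu_mine == pytest.approx(mu_cobra, rel=1e-6)


def test_flux_solution_accessors():
    sol = FluxSolution(1.0, "optimal", {"r": 2.0})
    assert sol["r"] == 2.0 and sol.optimal
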