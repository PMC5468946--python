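"""FBA/FVA formulation against analytic and brute-force oracles."""

import numpy as np
import pytest
from scipy.optimize import linprog

from adipoflux import (
    Metabolite,
    MetabolicNetwork,
    ObjectiveDefinition,
    Reaction,
    SolverStatus,
    solve_fba,
    solve_fva,
)
from adipoflux.lp import InfeasibleProblemError, max_flux_per_reaction

from conftest import make_chain_network, make_parallel_network
from helpers_oracles import fba_vertex_oracle, network_arrays


def _random_network(seed):
    """Small random network, always feasible (0 within every bound)."""
    rng = np.random.default_rng(seed)
    n_met, n_rxn = int(rng.integers(2, 5)), 8
    mets = [Metabolite(id=f"m{i}", compartment="c") for i in range(n_met)]
    rxns = []
    for j in range(n_rxn):
        size = int(rng.integers(1, min(3, n_met) + 1))
        chosen = rng.choice(n_met, size=size, replace=False)
        stoich = {f"m{i}": float(rng.choice([-2, -1, 1, 2])) for i in chosen}
        lo = float(rng.choice([-10.0, -5.0, 0.0]))
        hi = float(rng.choice([5.0, 10.0]))
        rxns.append(Reaction(f"r{j}", stoich, lo, hi))
    weights = {f"r{j}": 1.0 for j in rng.choice(n_rxn, size=2, replace=False)}
    net = MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        objectives={"obj": ObjectiveDefinition("obj", weights)},
    )
    net.validate()
    return net


class TestFBA:
    def test_chain_optimum_set_by_uptake(self, chain_network):
        res = solve_fba(chain_network, "drain")
        assert res.ok
        assert res.objective_value == pytest.approx(10.0, abs=1e-8)

    def test_bottleneck_bound_limits_optimum(self):
        res = solve_fba(make_chain_network(r1_upper=4.0), "drain")
        assert res.objective_value == pytest.approx(4.0, abs=1e-8)

    def test_minimize_sense(self, chain_network):
        res = solve_fba(chain_network, "drain", sense="minimize")
        assert res.objective_value == pytest.approx(0.0, abs=1e-8)

    def test_optimum_matches_vertex_enumeration_oracle(self):
        for seed in range(25):
            net = _random_network(seed)
            S, lb, ub, rxn_ids = network_arrays(net)
            c = np.zeros(len(rxn_ids))
            for rid, w in net.objectives["obj"].coefficients.items():
                c[rxn_ids.index(rid)] = w
            expected = fba_vertex_oracle(S, lb, ub, c)
            res = solve_fba(net, "obj")
            assert res.ok and expected is not None
            assert res.objective_value == pytest.approx(expected, abs=1e-6), seed

    def test_mass_balance_of_returned_fluxes(self):
        for seed in range(25):
            net = _random_network(seed)
            res = solve_fba(net, "obj")
            S, _, rxn_ids = net.stoichiometric_matrix()
            v = np.array([res.fluxes[r] for r in rxn_ids])
            assert np.max(np.abs(S @ v)) <= 1e-6
            lb = np.array([r.lower_bound for r in net.reactions])
            ub = np.array([r.upper_bound for r in net.reactions])
            assert np.all(v >= lb - 1e-6) and np.all(v <= ub + 1e-6)

    def test_relaxing_a_bound_never_decreases_optimum(self):
        for seed in range(10):
            net = _random_network(seed)
            base = solve_fba(net, "obj").objective_value
            relaxed = net.copy()
            rng = np.random.default_rng(seed)
            r = relaxed.reactions[int(rng.integers(len(relaxed.reactions)))]
            r.upper_bound += 5.0
            assert solve_fba(relaxed, "obj").objective_value >= base - 1e-9

    def test_infeasible_reported_not_zeroed(self):
        net = make_chain_network()
        # force uptake while the drain is closed: no steady state exists
        net.get_reaction("EX_A").upper_bound = -5.0
        net.get_reaction("EX_A").lower_bound = -5.0
        net.get_reaction("DM_B").upper_bound = 0.0
        net.get_reaction("R1").upper_bound = 0.0
        res = solve_fba(net, "drain")
        assert res.status == SolverStatus.INFEASIBLE
        assert res.objective_value is None

    def test_unknown_objective_name(self, chain_network):
        with pytest.raises(KeyError, match="no objective"):
            solve_fba(chain_network, "nope")


class TestFVA:
    def test_unique_optimum_pins_every_reaction(self, chain_network):
        fva = solve_fva(chain_network, "drain", fraction_of_optimum=1.0)
        for rid in ("EX_A", "R1", "DM_B"):
            lo, hi = fva[rid]
            assert abs(abs(lo) - 10.0) < 1e-6 and abs(abs(hi) - 10.0) < 1e-6

    def test_parallel_routes_are_interchangeable(self, parallel_network):
        fva = solve_fva(parallel_network, "drain", fraction_of_optimum=1.0)
        assert fva["R1"] == pytest.approx((0.0, 10.0), abs=1e-6)
        assert fva["R2"] == pytest.approx((0.0, 10.0), abs=1e-6)

    def test_fraction_zero_equals_independent_min_max_lps(self):
        for seed in range(5):
            net = _random_network(seed)
            fva = solve_fva(net, "obj", fraction_of_optimum=0.0)
            S, lb, ub, rxn_ids = network_arrays(net)
            bounds = list(zip(lb, ub))
            for j, rid in enumerate(rxn_ids):
                e = np.zeros(len(rxn_ids))
                e[j] = 1.0
                lo = linprog(e, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                             method="highs").fun
                hi = -linprog(-e, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                              method="highs").fun
                assert fva[rid][0] == pytest.approx(lo, abs=1e-6)
                assert fva[rid][1] == pytest.approx(hi, abs=1e-6)

    def test_ranges_nest_as_fraction_rises(self):
        for seed in range(10):
            net = _random_network(seed)
            tight = solve_fva(net, "obj", fraction_of_optimum=1.0)
            loose = solve_fva(net, "obj", fraction_of_optimum=0.9)
            for rid in tight.ranges:
                assert tight[rid][0] >= loose[rid][0] - 1e-6
                assert tight[rid][1] <= loose[rid][1] + 1e-6

    def test_infeasible_base_aborts_before_subproblems(self):
        net = make_chain_network()
        net.get_reaction("EX_A").lower_bound = -5.0
        net.get_reaction("EX_A").upper_bound = -5.0
        net.get_reaction("R1").upper_bound = 0.0
        net.get_reaction("R1").lower_bound = 0.0
        with pytest.raises(InfeasibleProblemError):
            solve_fva(net, "drain")

    def test_invalid_fraction_rejected(self, chain_network):
        with pytest.raises(ValueError):
            solve_fva(chain_network, "drain", fraction_of_optimum=1.5)


def test_max_flux_per_reaction_covers_both_objectives(synthetic_net_truth):
    net, _ = synthetic_net_truth
    caps = max_flux_per_reaction(net, ["biomass", "lipid_droplet"])
    # the biomass drain is closed at the lipid optimum and vice versa, but
    # the elementwise max keeps both reachable
    assert caps["DM_biomass"] == pytest.approx(40.0, abs=1e-6)
    assert caps["DM_lipid"] == pytest.approx(40.0, abs=1e-6)
    assert all(v >= -1e-9 for v in caps.values())
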