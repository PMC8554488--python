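"""Objective arithmetic, solver correctness, and ensemble behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicsforest.pcsf import (
    COST_FLOOR,
    ForestSolution,
    Hyperparameters,
    Interactome,
    PrizeMap,
    brute_force_pcsf,
    edge_cost,
    forest_objective,
    force_include,
    regularized_edge_cost,
    robustness_ensemble,
    select_parameters,
    solve_pcsf,
    specificity_ensemble,
)


def _random_instance(rng, n_min=4, n_max=11):
    n = int(rng.integers(n_min, n_max))
    nodes = [f"N{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j], float(rng.uniform(0.05, 1.0)))
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < 0.45
    ]
    present = {u for e in edges for u in e[:2]}
    for k in range(n - 1):  # spanning chain keeps every node in play
        if nodes[k] not in present or nodes[k + 1] not in present or k == 0:
            edges.append((nodes[k], nodes[k + 1], float(rng.uniform(0.05, 1.0))))
    seen = set()
    dedup = []
    for u, v, s in edges:
        key = tuple(sorted((u, v)))
        if key not in seen:
            seen.add(key)
            dedup.append((u, v, s))
    net = Interactome(dedup)
    prizes = PrizeMap(prizes={v: float(rng.uniform(0, 2)) for v in net.nodes})
    params = Hyperparameters(
        beta=float(rng.choice([0.5, 1, 2])),
        omega=float(rng.choice([0.05, 0.5])),
        alpha=float(rng.choice([0, 1])),
    )
    return net, prizes, params


class TestEdgeCosts:
    def test_full_confidence_hits_the_floor(self):
        assert edge_cost(1.0) == COST_FLOOR

    def test_cost_is_one_minus_confidence(self):
        assert edge_cost(0.3) == pytest.approx(0.7)

    def test_cost_monotone_decreasing_in_confidence(self):
        s = np.linspace(0.01, 1.0, 50)
        c = [edge_cost(x) for x in s]
        assert all(c1 >= c2 for c1, c2 in zip(c, c[1:]))

    def test_out_of_range_confidence_rejected(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                edge_cost(bad)

    def test_printed_formula_substitution(self):
        # N=4, da=db=1: penalty = 1*1 / (2*2 + 1) = 1/5
        assert regularized_edge_cost(0.5, 1, 1, 4, 1.0) == pytest.approx(0.7)

    def test_penalty_saturates_at_alpha_for_max_degree(self):
        for n in (5, 20, 101):
            assert regularized_edge_cost(0.0, n - 1, 3, n, 2.5) == pytest.approx(2.5)

    def test_zero_alpha_leaves_cost_unchanged(self):
        assert regularized_edge_cost(0.42, 3, 7, 20, 0.0) == 0.42

    def test_inconsistent_degrees_rejected(self):
        with pytest.raises(ValueError):
            regularized_edge_cost(0.1, 0, 2, 5, 1.0)
        with pytest.raises(ValueError):
            regularized_edge_cost(0.1, 5, 2, 5, 1.0)

    @settings(deadline=None, max_examples=300)
    @given(
        st.integers(3, 500),
        st.integers(1, 499),
        st.integers(1, 499),
        st.floats(0.01, 10),
    )
    def test_penalty_bounded_and_monotone(self, n, da, db, alpha):
        da, db = min(da, n - 1), min(db, n - 1)
        pen = regularized_edge_cost(0.0, da, db, n, alpha)
        assert 0 <= pen <= alpha + 1e-12
        if da < n - 1:
            assert regularized_edge_cost(0.0, da + 1, db, n, alpha) >= pen - 1e-12


class TestObjective:
    NET = Interactome([("A", "B", 0.8), ("B", "C", 0.1)])  # costs 0.2, 0.9
    PRIZES = PrizeMap(prizes={"A": 1.0, "B": 0.0, "C": 0.5})

    def test_empty_forest_scores_zero(self):
        empty = ForestSolution((), (), 0, 0.0, {})
        params = Hyperparameters(beta=1, omega=0.1)
        assert forest_objective(empty, self.PRIZES, params, self.NET) == 0.0

    def test_single_node_tree(self):
        sol = ForestSolution(("A",), (), 1, 0.0, {"A": "prize"})
        params = Hyperparameters(beta=2, omega=0.1)
        assert forest_objective(sol, self.PRIZES, params, self.NET) == pytest.approx(1.9)

    def test_two_singletons_value_matches_enumeration(self):
        sol = ForestSolution(("A", "C"), (), 2, 0.0, {})
        params = Hyperparameters(beta=1, omega=0.1)
        assert forest_objective(sol, self.PRIZES, params, self.NET) == pytest.approx(1.3)

    def test_unknown_edge_rejected(self):
        sol = ForestSolution(("A", "C"), (("A", "C"),), 1, 0.0, {})
        with pytest.raises(ValueError):
            forest_objective(sol, self.PRIZES, Hyperparameters(), self.NET)


class TestBruteForce:
    def test_three_node_example_optimum_is_two_singletons(self):
        net = TestObjective.NET
        prizes = TestObjective.PRIZES
        params = Hyperparameters(beta=1, omega=0.1)
        best = brute_force_pcsf(net, prizes, params)
        assert set(best.nodes) == {"A", "C"}
        assert best.edges == ()
        assert best.objective == pytest.approx(1.3)

    def test_all_zero_prizes_gives_empty_forest(self):
        net = TestObjective.NET
        prizes = PrizeMap(prizes={v: 0.0 for v in net.nodes})
        best = brute_force_pcsf(net, prizes, Hyperparameters(beta=1, omega=0.1))
        assert best.nodes == () and best.objective == 0.0

    def test_huge_omega_empties_the_forest(self):
        net = TestObjective.NET
        prizes = TestObjective.PRIZES
        params = Hyperparameters(beta=1, omega=10.0)
        best = brute_force_pcsf(net, prizes, params)
        assert best.nodes == ()

    def test_size_guard(self):
        edges = [(f"N{i}", f"N{i+1}", 0.5) for i in range(20)]
        with pytest.raises(ValueError):
            brute_force_pcsf(
                Interactome(edges), PrizeMap(prizes={}), Hyperparameters()
            )


class TestHeuristicSolver:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(12)
        for trial in range(40):
            net, prizes, params = _random_instance(rng)
            bf = brute_force_pcsf(net, prizes, params)
            heur = solve_pcsf(net, prizes, params, seed=trial)
            assert heur.objective == pytest.approx(bf.objective, abs=1e-9)

    def test_beta_zero_gives_empty_forest(self):
        rng = np.random.default_rng(1)
        net, prizes, _ = _random_instance(rng)
        sol = solve_pcsf(net, prizes, Hyperparameters(beta=0, omega=0.1), seed=0)
        assert sol.nodes == ()

    def test_solution_is_a_structural_forest(self):
        import networkx as nx

        rng = np.random.default_rng(3)
        for trial in range(10):
            net, prizes, params = _random_instance(rng, n_min=8, n_max=12)
            sol = solve_pcsf(net, prizes, params, seed=trial)
            g = nx.Graph()
            g.add_nodes_from(sol.nodes)
            g.add_edges_from(sol.edges)
            if g.number_of_nodes():
                assert nx.is_forest(g)
                assert nx.number_connected_components(g) == sol.n_trees
            for v in sol.steiner_nodes():
                assert g.degree[v] >= 1

    def test_captured_prize_mass_nondecreasing_in_beta(self):
        rng = np.random.default_rng(21)
        for trial in range(15):
            net, prizes, params = _random_instance(rng)
            masses = []
            for beta in (0.5, 1.0, 2.0):
                sol = brute_force_pcsf(
                    net, prizes,
                    Hyperparameters(beta=beta, omega=params.omega, alpha=params.alpha),
                )
                masses.append(beta * sum(prizes.get(v) for v in sol.nodes))
            assert masses == sorted(masses)


class TestForcing:
    def test_forced_node_enters_solution(self):
        rng = np.random.default_rng(31)
        for trial in range(20):
            net, prizes, params = _random_instance(rng)
            target = net.nodes[int(rng.integers(len(net.nodes)))]
            forced = force_include(prizes, target, net)
            if params.beta == 0:
                continue
            sol = solve_pcsf(net, forced, params, seed=trial)
            assert target in sol.nodes
            assert sol.provenance[target] == "prize"

    def test_forcing_strictly_increases_even_the_max_prize(self):
        net = TestObjective.NET
        prizes = PrizeMap(prizes={"A": 3.0, "B": 1.0})
        forced = force_include(prizes, "A", net)
        assert forced.prizes["A"] == pytest.approx(30.0)
        twice = force_include(forced, "A", net)
        assert twice.prizes["A"] == pytest.approx(300.0)
        assert forced.provenance["A"] == "forced"

    def test_unknown_node_rejected(self):
        with pytest.raises(ValueError):
            force_include(TestObjective.PRIZES, "nope", TestObjective.NET)


class TestEnsembles:
    def _instance(self):
        rng = np.random.default_rng(77)
        nodes = [f"N{i}" for i in range(12)]
        edges = [
            (nodes[i], nodes[j], float(rng.uniform(0.3, 0.9)))
            for i in range(12)
            for j in range(i + 1, 12)
            if rng.random() < 0.4 or j == i + 1
        ]
        net = Interactome(edges)
        prizes = PrizeMap(
            prizes={v: (2.0 if int(v[1:]) < 4 else 0.0) for v in net.nodes}
        )
        return net, prizes

    def test_zero_noise_makes_all_frequencies_unit(self):
        net, prizes = self._instance()
        params = Hyperparameters(beta=1, omega=0.1, noise_sd=0.0, reps=5, top_k=4)
        summary = robustness_ensemble(net, prizes, params, seed=0)
        included = {v for v, f in summary.inclusion_frequency.items() if f > 0}
        assert all(summary.inclusion_frequency[v] == 1.0 for v in included)

    def test_ensembles_are_bit_reproducible(self):
        net, prizes = self._instance()
        params = Hyperparameters(beta=1, omega=0.1, noise_sd=0.3, reps=8, top_k=4)
        a = robustness_ensemble(net, prizes, params, seed=5)
        b = robustness_ensemble(net, prizes, params, seed=5)
        assert a.inclusion_frequency == b.inclusion_frequency
        assert a.selected == b.selected
        sa = specificity_ensemble(net, prizes, params, seed=5)
        sb = specificity_ensemble(net, prizes, params, seed=5)
        assert sa == sb

    def test_single_rep_specificity_frequencies_are_binary(self):
        net, prizes = self._instance()
        params = Hyperparameters(beta=1, omega=0.1, reps=1)
        freq = specificity_ensemble(net, prizes, params, seed=2)
        assert set(freq.values()) <= {0.0, 1.0}

    def test_module_nodes_outrank_background_in_frequency(self, small_bundle):
        params = Hyperparameters(beta=1, omega=0.1, alpha=1, noise_sd=0.3, reps=10,
                                 top_k=10)
        summary = robustness_ensemble(
            small_bundle.interactome, small_bundle.prizes, params, seed=1
        )
        truth = small_bundle.truth["module_nodes"]
        freq = summary.inclusion_frequency
        module_mean = np.mean([freq[v] for v in truth])
        other_mean = np.mean([freq[v] for v in freq if v not in truth])
        assert module_mean > other_mean


class TestParameterSelection:
    def _instance(self):
        edges = [
            ("A", "B", 0.9),
            ("B", "C", 0.9),
            ("C", "D", 0.9),
            ("D", "E", 0.9),
            ("E", "F", 0.9),
        ]
        net = Interactome(edges)
        # one prize too small to pay for itself at beta=1, omega=0.5
        prizes = PrizeMap(prizes={"A": 2.0, "C": 2.0, "F": 0.1})
        return net, prizes

    def test_single_passing_setting_is_returned(self):
        net, prizes = self._instance()
        grid = [Hyperparameters(beta=1, omega=0.5, reps=5)]
        result = select_parameters(grid, net, prizes, spec_threshold=1.0,
                                   deg_threshold=1.0, seed=0)
        assert result["chosen"] is grid[0]
        assert result["diagnostics"][0]["feature_selection"]

    def test_settings_retaining_everything_are_rejected(self):
        net, prizes = self._instance()
        grid = [Hyperparameters(beta=100, omega=0.01, reps=5)]
        result = select_parameters(grid, net, prizes, spec_threshold=1.0,
                                   deg_threshold=1.0, seed=0)
        assert result["chosen"] is None
        assert not result["diagnostics"][0]["feature_selection"]

    def test_relaxed_thresholds_pass_specificity_and_degree(self):
        net, prizes = self._instance()
        grid = [Hyperparameters(beta=1, omega=0.5, reps=5)]
        result = select_parameters(grid, net, prizes, spec_threshold=1.0,
                                   deg_threshold=1.0, seed=0)
        diag = result["diagnostics"][0]
        assert diag["specific"] and diag["degree_matched"]
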