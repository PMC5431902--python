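"""Tree container, parsimony, Mk1 likelihood, simulation and mapping."""
import math

import numpy as np
import pytest

import beecastes as bc
from beecastes.phylo import (_mk1_Q, BRANCH_LENGTH_FLOOR, MappingError,
                             RATE_LOWER, transition_matrices,
                             validate_rate_matrix)
from beecastes.synth import random_bifurcating_tree

from conftest import brute_force_fitch, brute_force_vcv, enumeration_loglik


class TestNewick:
    def test_minimal_two_tip(self):
        t = bc.parse_newick("(A:1,B:1):0;")
        assert sorted(t.tip_labels) == ["A", "B"]
        assert all(t.length[i] == 1 for i in t.tip_ids)

    def test_three_tip_structure(self, three_tip):
        t = three_tip
        a, b = t.tip_id("A"), t.tip_id("B")
        assert t.parent[a] == t.parent[b] != t.root
        assert t.node_depths()[t.tip_id("C")] == 2

    def test_roundtrip_preserves_topology_and_lengths(self, rng):
        for seed in range(5):
            t = random_bifurcating_tree(9, seed=seed)
            t2 = bc.parse_newick(t.to_newick())
            assert sorted(t2.tip_labels) == sorted(t.tip_labels)
            assert np.allclose(np.sort(t2.length), np.sort(t.length))
            assert np.allclose(bc.vcv_matrix(t2), bc.vcv_matrix(t))

    def test_malformed_raises(self):
        with pytest.raises(bc.NewickError):
            bc.parse_newick("((A:1,B:1:0;")

    def test_duplicate_tips_raise(self):
        with pytest.raises(bc.NewickError, match="duplicate"):
            bc.parse_newick("(A:1,A:1):0;")

    def test_fixture_tree_tips_are_the_study_species(self, study):
        assert study.tree.n_tips == 28
        assert {bc.tip_label(s) for s in study.table["species"]} \
            == set(study.tree.tip_labels)

    def test_polytomy_resolution_bifurcates_preserving_depths(self):
        t = bc.parse_newick("(A:1,B:1,C:1,D:1):0;")
        assert not t.is_bifurcating()
        r = t.resolve_polytomies()
        assert r.is_bifurcating()
        d = r.node_depths()
        assert all(d[r.tip_id(x)] == 1 for x in "ABCD")


class TestVCV:
    def test_star_tree_no_shared_history(self):
        t = bc.parse_newick("(A:3,B:3,C:3):0;")
        V = bc.vcv_matrix(t)
        assert np.allclose(V, 3 * np.eye(3))

    def test_three_tip_by_hand(self, three_tip):
        V = bc.vcv_matrix(three_tip)
        i = {l: k for k, l in enumerate(three_tip.tip_labels)}
        assert V[i["A"], i["A"]] == 2
        assert V[i["A"], i["B"]] == 1
        assert V[i["A"], i["C"]] == 0

    def test_matches_brute_force_path_enumeration(self):
        for seed in range(4):
            t = random_bifurcating_tree(10, seed=seed)
            assert np.allclose(bc.vcv_matrix(t), brute_force_vcv(t), atol=1e-12)

    def test_positive_semidefinite(self):
        for seed in range(10):
            t = random_bifurcating_tree(12, seed=100 + seed)
            ev = np.linalg.eigvalsh(bc.vcv_matrix(t))
            assert ev.min() >= -1e-9


class TestFitch:
    def test_constant_character_needs_no_change(self, four_tip):
        states = bc.BinaryStateVector({l: 0 for l in four_tip.tip_labels})
        assert bc.fitch_count(four_tip, states) == 0

    def test_single_autapomorphy(self, four_tip):
        s = {l: 0 for l in four_tip.tip_labels}
        s["A"] = 1
        assert bc.fitch_count(four_tip, bc.BinaryStateVector(s)) == 1

    def test_matches_exhaustive_minimum_on_random_trees(self, rng):
        for seed in range(8):
            t = random_bifurcating_tree(8, seed=300 + seed)
            x = rng.integers(0, 2, size=8)
            states = bc.BinaryStateVector(dict(zip(t.tip_labels, map(int, x))))
            assert bc.fitch_count(t, states) == brute_force_fitch(t, x)

    def test_unassigned_tip_errors(self, four_tip):
        with pytest.raises(ValueError, match="without a state"):
            bc.fitch_count(four_tip, bc.BinaryStateVector({"A": 1}))


class TestMk1:
    def test_identical_tips_low_rate_certain_root(self):
        t = bc.parse_newick("(A:1,B:1):0;")
        fit = bc.mk1_fit(t, bc.BinaryStateVector({"A": 1, "B": 1}))
        assert fit.degenerate and fit.rate == RATE_LOWER
        assert fit.marginal_node_probabilities[t.root] > 0.999

    @pytest.mark.parametrize("seed", range(6))
    def test_pruning_equals_enumeration(self, seed, rng):
        n = int(rng.integers(3, 7))
        t = random_bifurcating_tree(n, seed=400 + seed)
        x = rng.integers(0, 2, size=n)
        while len(set(x)) < 2:
            x = rng.integers(0, 2, size=n)
        q = float(rng.uniform(0.05, 1.5))
        ours = bc.pruning_loglik(t, x, _mk1_Q(q))
        brute = enumeration_loglik(t, x, _mk1_Q(q))
        assert ours == pytest.approx(brute, abs=1e-10)

    def test_label_swap_symmetry(self, rng):
        t = random_bifurcating_tree(8, seed=11)
        x = rng.integers(0, 2, size=8)
        for q in (0.05, 0.5):
            assert bc.pruning_loglik(t, x, _mk1_Q(q)) == pytest.approx(
                bc.pruning_loglik(t, 1 - x, _mk1_Q(q)), abs=1e-12)

    def test_ml_rate_median_unbiased(self):
        # simulate at a known rate, refit: median within 15% over replicates
        t = random_bifurcating_tree(20, seed=5, ultrametric=True)
        scale = t.node_depths().max()
        true_rate = 3.0 / scale  # a few expected changes over the tree
        Q = true_rate * np.array([[-1.0, 1.0], [1.0, -1.0]])
        est = []
        for i in range(200):
            h = bc.simulate_discrete(t, Q, seed=6000 + i)
            tips = h.tip_states()
            if len(set(tips.values())) < 2:
                continue
            est.append(bc.mk1_fit(t, bc.BinaryStateVector(tips)).rate)
        assert abs(np.median(est) - true_rate) / true_rate < 0.15

    def test_marginals_are_probabilities(self, study):
        fit = bc.mk1_fit(study.tree, study.larger_guards)
        p = np.array(list(fit.marginal_node_probabilities.values()))
        assert ((p >= 0) & (p <= 1)).all()
        assert fit.log_likelihood <= 0


class TestSimulateDiscrete:
    def test_zero_rates_freeze_root_state(self, four_tip):
        h = bc.simulate_discrete(four_tip, np.zeros((2, 2)), seed=0)
        assert len(set(h.node_states)) == 1
        assert all(not ev for ev in h.events)

    def test_nonconservative_q_rejected(self, four_tip):
        with pytest.raises(ValueError, match="sum to 0"):
            bc.simulate_discrete(four_tip, np.array([[0.0, 1.0], [1.0, -1.0]]))
        with pytest.raises(ValueError, match=">= 0"):
            bc.simulate_discrete(four_tip, np.array([[1.0, -1.0], [1.0, -1.0]]))

    def test_long_branch_reaches_stationarity(self):
        t = bc.parse_newick("(A:200,B:200):0;")
        Q = 0.5 * np.array([[-1.0, 1.0], [1.0, -1.0]])
        ones = sum(bc.simulate_discrete(t, Q, seed=i).tip_states()["A"]
                   for i in range(400))
        assert abs(ones / 400 - 0.5) < 3 * 0.5 / math.sqrt(400)

    def test_tip_frequencies_match_analytic_transition_probabilities(self, four_tip):
        # P(tip=1 | root) composed along the path must match simulation
        q = 0.3
        Q = _mk1_Q(q)
        n = 2000
        counts = {l: 0 for l in four_tip.tip_labels}
        for i in range(n):
            h = bc.simulate_discrete(four_tip, Q, root_prior=[1.0, 0.0],
                                     seed=700 + i)
            for l, s in h.tip_states().items():
                counts[l] += s
        depths = four_tip.node_depths()
        for l in four_tip.tip_labels:
            p1 = 0.5 - 0.5 * math.exp(-2 * q * depths[four_tip.tip_id(l)])
            se = math.sqrt(p1 * (1 - p1) / n)
            assert abs(counts[l] / n - p1) <= 3 * se


class TestCountOrigins:
    def test_constant_history_zero(self, four_tip):
        h = bc.simulate_discrete(four_tip, np.zeros((2, 2)), root_prior=[1, 0],
                                 seed=1)
        assert bc.count_origins(h) == 0

    def test_matches_event_scan(self, four_tip, rng):
        Q = _mk1_Q(0.4)
        for i in range(20):
            h = bc.simulate_discrete(four_tip, Q, seed=900 + i)
            manual = 0
            for v, ev in enumerate(h.events):
                s = int(h.node_states[h.tree.parent[v]]) if h.tree.parent[v] >= 0 else None
                for _, new in ev:
                    manual += (s == 0 and new == 1)
                    s = new
            assert bc.count_origins(h) == manual


class TestStochasticMap:
    def test_uniform_ones_give_certain_history(self):
        t = bc.parse_newick("((A:1,B:1):1,(C:1,D:1):1):0;")
        states = bc.BinaryStateVector({l: 1 for l in t.tip_labels})
        sm = bc.stochastic_map(t, states, n_sim=200, seed=1)
        assert all(p > 0.99 for p in sm.node_posterior.values())
        assert sm.modal_origin_count == 0  # root starts in state 1

    def test_origin_distribution_sums_to_n_sim(self, study):
        sm = bc.stochastic_map(study.tree, study.larger_guards, n_sim=50, seed=2)
        assert sum(sm.origin_count_distribution.values()) == 50
        assert all(0 <= v <= 1 for v in sm.branch_state_density.values())

    def test_node_posteriors_track_mk1_marginals(self, four_tip):
        states = bc.BinaryStateVector({"A": 1, "B": 1, "C": 0, "D": 0})
        fit = bc.mk1_fit(four_tip, states)
        sm = bc.stochastic_map(four_tip, states, n_sim=3000, seed=3,
                               rate=fit.rate)
        for v, post in sm.node_posterior.items():
            p = fit.marginal_node_probabilities[v]
            se = math.sqrt(max(p * (1 - p), 1e-12) / 3000)
            assert abs(post - p) <= max(3 * se, 0.01)

    def test_determinism_same_seed(self, four_tip):
        states = bc.BinaryStateVector({"A": 1, "B": 0, "C": 0, "D": 1})
        a = bc.stochastic_map(four_tip, states, n_sim=100, seed=9)
        b = bc.stochastic_map(four_tip, states, n_sim=100, seed=9)
        assert a.to_json_dict() == b.to_json_dict()


def test_transition_matrices_rows_sum_to_one(rng):
    Q = validate_rate_matrix(np.array([[-0.3, 0.2, 0.1, 0.0],
                                       [0.4, -0.5, 0.0, 0.1],
                                       [0.2, 0.0, -0.9, 0.7],
                                       [0.0, 0.3, 0.3, -0.6]]))
    P = transition_matrices(Q, rng.uniform(0.01, 50, size=12))
    assert np.allclose(P.sum(axis=2), 1.0, atol=1e-9)
    assert (P >= 0).all()
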