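import numpy as np
import pytest

from helpers import ForcedRNG, enumerate_dags
from ilsbn.dag_core import (
    DAG,
    MalformedStructureError,
    is_acyclic,
    leaf_nodes,
    max_in_degree,
    max_out_degree,
    random_dag,
    root_nodes,
    shd_pair,
)
from ilsbn.operators import (
    apply_basic,
    effect_trials,
    leaf_move,
    leaf_op,
    momentum,
    parse_operator_spec,
    perturb,
    replay,
    root_op,
    swap_candidates,
    swap_move,
    swap_op,
    swap_pairs,
)


def star_out(u: int) -> DAG:
    """Hub with u children: the maximal-impact target for Leaf."""
    nodes = ("HUB",) + tuple(f"c{i}" for i in range(u))
    return DAG(nodes, [("HUB", c) for c in nodes[1:]])


def collider_in(k: int) -> DAG:
    """Sink with k parents: the maximal-impact target for Root."""
    nodes = tuple(f"p{i}" for i in range(k)) + ("SINK",)
    return DAG(nodes, [(p, "SINK") for p in nodes[:-1]])


class TestApplyBasic:
    def test_add_simple(self):
        g = apply_basic(DAG(("A", "B")), "add", ("A", "B"))
        assert g.edges == {("A", "B")}

    def test_add_closing_cycle_is_reversed(self, chain3):
        g = apply_basic(chain3, "add", ("C", "A"))
        assert g.edges == {("A", "B"), ("B", "C"), ("A", "C")}

    def test_add_over_adjacency_rejected(self, chain3):
        with pytest.raises(MalformedStructureError):
            apply_basic(chain3, "add", ("B", "A"))

    def test_delete(self, chain3):
        g = apply_basic(chain3, "delete", ("A", "B"))
        assert g.edges == {("B", "C")}

    def test_delete_missing_rejected(self, chain3):
        with pytest.raises(MalformedStructureError):
            apply_basic(chain3, "delete", ("A", "C"))

    def test_reverse_accepted(self, chain3):
        g = apply_basic(chain3, "reverse", ("A", "B"))
        assert g.edges == {("B", "A"), ("B", "C")}

    def test_reverse_closing_cycle_is_dropped(self):
        g0 = DAG(("A", "B", "C"), [("A", "B"), ("A", "C"), ("C", "B")])
        g = apply_basic(g0, "reverse", ("A", "B"))
        assert g.edges == g0.edges

    def test_input_never_mutated(self, chain3):
        before = chain3.edges
        apply_basic(chain3, "delete", ("A", "B"))
        assert chain3.edges == before


class TestLeafRoot:
    def test_leaf_asia_reverses_two_edges(self, asia_dag):
        g = leaf_op(asia_dag, "E")
        assert g.has_edge("X", "E") and g.has_edge("D", "E")
        assert g.out_degree("E") == 0
        assert shd_pair(asia_dag, g) == 2

    def test_root_asia_reverses_two_edges(self, asia_dag):
        g = root_op(asia_dag, "E")
        assert g.has_edge("E", "T") and g.has_edge("E", "L")
        assert g.in_degree("E") == 0
        assert shd_pair(asia_dag, g) == 2

    def test_leaf_of_leaf_is_noop(self, asia_dag):
        assert leaf_op(asia_dag, "X") == asia_dag

    def test_root_of_root_is_noop(self, asia_dag):
        assert root_op(asia_dag, "A") == asia_dag

    def test_unknown_node_rejected(self, asia_dag):
        with pytest.raises(MalformedStructureError):
            leaf_op(asia_dag, "ZZ")
        with pytest.raises(MalformedStructureError):
            root_op(asia_dag, "ZZ")

    def test_idempotence(self, asia_dag):
        once = leaf_op(asia_dag, "E")
        assert leaf_op(once, "E") == once
        ronce = root_op(asia_dag, "E")
        assert root_op(ronce, "E") == ronce

    def test_star_leaf_effect_equals_out_degree(self):
        g = star_out(7)
        assert shd_pair(g, leaf_op(g, "HUB")) == 7 == max_out_degree(g)

    def test_collider_root_effect_equals_in_degree(self):
        g = collider_in(5)
        assert shd_pair(g, root_op(g, "SINK")) == 5 == max_in_degree(g)

    def test_acyclicity_exhaustive_small_graphs(self):
        # Leaf/Root preserve acyclicity: every node of every DAG on <= 4 nodes
        for nodes in [("A", "B", "C"), ("A", "B", "C", "D")]:
            for g in enumerate_dags(nodes):
                for x in nodes:
                    assert is_acyclic(leaf_op(g, x).edges, nodes)
                    assert is_acyclic(root_op(g, x).edges, nodes)

    def test_acyclicity_random_larger_graphs(self):
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 25))
            nodes = tuple(f"v{i}" for i in range(n))
            g = random_dag(nodes, 0.2, rng)
            x = nodes[int(rng.integers(n))]
            assert is_acyclic(leaf_op(g, x).edges, nodes)
            assert is_acyclic(root_op(g, x).edges, nodes)

    def test_effect_intervals(self):
        # 1 <= SHD(Leaf(G,x), G) <= u for non-leaves; mirror for Root
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            nodes = tuple(f"v{i}" for i in range(8))
            g = random_dag(nodes, 0.3, rng)
            u, k = max_out_degree(g), max_in_degree(g)
            for x in nodes:
                if x not in leaf_nodes(g):
                    assert 1 <= shd_pair(g, leaf_op(g, x)) <= u
                if x not in root_nodes(g):
                    assert 1 <= shd_pair(g, root_op(g, x)) <= k


class TestSwap:
    def test_asia_whitelist_contains_b_for_t(self, asia_dag):
        assert "B" in swap_candidates(asia_dag, "T")

    def test_no_parents_means_empty_whitelist(self, asia_dag):
        assert swap_candidates(asia_dag, "A") == []

    def test_shared_only_parent_excluded(self):
        g = DAG(("P", "X", "Y"), [("P", "X"), ("P", "Y")])
        assert swap_candidates(g, "X") == []

    def test_self_loop_pair_excluded(self):
        # the only exchange for (X, Y) would create Y -> Y
        g = DAG(("P", "X", "Y"), [("Y", "X"), ("P", "Y")])
        assert swap_pairs(g, "X", "Y") == []

    def test_duplicate_edge_pair_excluded(self):
        # P -> y already exists, so exchanging P->x with Q->y is banned
        g = DAG(("P", "Q", "X", "Y"), [("P", "X"), ("Q", "Y"), ("P", "Y")])
        assert ("P", "Q") not in swap_pairs(g, "X", "Y")

    def test_bidirectional_pair_excluded(self):
        # new edge Q -> x would oppose the existing x -> Q
        g = DAG(("P", "Q", "X", "Y"), [("P", "X"), ("Q", "Y"), ("X", "Q")])
        assert swap_pairs(g, "X", "Y") == []

    def test_asia_swap_t_b(self, asia_dag):
        g = swap_op(asia_dag, "T", "B", np.random.default_rng(0))
        assert g.has_edge("A", "B") and g.has_edge("S", "T")
        assert not g.has_edge("A", "T") and not g.has_edge("S", "B")
        assert shd_pair(asia_dag, g) == 4

    def test_chain_swap_triggers_leaf_repair(self):
        # Swap(B, E) on A->B->C->D->E exchanges A->B, D->E into A->E, D->B;
        # D->B closes the cycle D->B->C->D, repaired by Leaf(D)
        g0 = DAG(tuple("ABCDE"), [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])
        mv = swap_move(g0, "B", "E", np.random.default_rng(0))
        g = replay(g0, mv)
        assert g.edges == {("A", "E"), ("B", "C"), ("B", "D"), ("C", "D")}
        assert ("reverse", "D", "B") in mv.trail

    def test_illegal_pair_rejected(self, asia_dag):
        with pytest.raises(MalformedStructureError):
            swap_op(asia_dag, "T", "A", np.random.default_rng(0))  # A has no parents

    def test_exhaustive_four_node_swaps(self):
        # every legal swap on every 4-node DAG: acyclic result, no invariant
        # violations, SHD exactly 4 without repair and within [4, 4+2u] always
        nodes = ("A", "B", "C", "D")
        rng = np.random.default_rng(0)
        seen = 0
        for g in enumerate_dags(nodes):
            u = max_out_degree(g)
            for x in nodes:
                for y in swap_candidates(g, x):
                    for pair in swap_pairs(g, x, y):
                        mv = swap_move(g, x, y, rng, pair=pair)
                        out = replay(g, mv)  # DAG constructor re-validates
                        d = shd_pair(g, out)
                        assert 4 <= d <= 4 + 2 * u
                        if len(mv.trail) == 4:  # no repair happened
                            assert d == 4
                        seen += 1
        assert seen > 200  # 216 legal (graph, x, y, pair) swaps on 4 nodes

    def test_move_replay_reproduces_post_state(self, asia_dag):
        mv = swap_move(asia_dag, "T", "B", np.random.default_rng(3))
        out = replay(asia_dag, mv)
        assert out == swap_op(asia_dag, "T", "B", pair=("A", "S"))
        # repair case: the recorded trail reproduces the repaired post-state
        g0 = DAG(tuple("ABCDE"), [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])
        mv2 = swap_move(g0, "B", "E", np.random.default_rng(0))
        assert replay(g0, mv2).edges == {("A", "E"), ("B", "C"), ("B", "D"), ("C", "D")}


class TestMomentumAndPerturb:
    def test_momentum_zero_is_identity(self, asia_dag):
        assert momentum(asia_dag, 0, np.random.default_rng(0)) == asia_dag

    def test_momentum_forced_leaf_e_matches_leaf_result(self, asia_dag):
        # force op=Leaf (index 0) on node E (index 3 of sorted labels)
        rng = ForcedRNG([0, sorted(asia_dag.nodes).index("E")])
        assert momentum(asia_dag, 1, rng) == leaf_op(asia_dag, "E")

    def test_momentum_results_acyclic(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            nodes = tuple(f"v{i}" for i in range(10))
            g = random_dag(nodes, 0.25, rng)
            out = momentum(g, g.n, rng)
            assert is_acyclic(out.edges, nodes)

    def test_momentum_negative_rejected(self, asia_dag):
        with pytest.raises(ValueError):
            momentum(asia_dag, -1, np.random.default_rng(0))

    def test_perturb_zero_is_identity(self, asia_dag):
        assert perturb(asia_dag, 0, np.random.default_rng(0)) == asia_dag

    def test_perturb_forced_delete_empties_single_edge_graph(self):
        g = DAG(("A", "B"), [("A", "B")])
        # basic kinds are (add, delete, reverse): force kind 1, edge 0
        out = perturb(g, 1, ForcedRNG([1, 0]))
        assert out.n_edges == 0

    def test_perturb_results_acyclic(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            nodes = tuple(f"v{i}" for i in range(9))
            g = random_dag(nodes, 0.25, rng)
            out = perturb(g, 3 * g.n, rng)
            assert is_acyclic(out.edges, nodes)


class TestEffectTrials:
    def test_basic_operators_always_one_unit(self, asia_dag):
        rng = np.random.default_rng(0)
        for op in ("add", "delete", "reverse"):
            stats = effect_trials(asia_dag, op, 5 * asia_dag.n, rng)
            assert stats == {"max": 1.0, "min": 1.0, "mean": 1.0}

    def test_swap_minimum_is_four(self, asia_dag):
        stats = effect_trials(asia_dag, "swap", 5 * asia_dag.n, np.random.default_rng(1))
        assert stats["min"] == 4.0
        assert stats["max"] >= 4.0

    def test_leaf_max_reaches_out_degree_on_star(self):
        g = star_out(6)
        stats = effect_trials(g, "leaf", 5 * g.n, np.random.default_rng(2))
        assert stats["max"] == max_out_degree(g) == 6
        assert stats["min"] >= 1.0

    def test_root_max_reaches_in_degree_on_collider(self):
        g = collider_in(5)
        stats = effect_trials(g, "root", 5 * g.n, np.random.default_rng(3))
        assert stats["max"] == max_in_degree(g) == 5

    def test_multi_object_spec(self, asia_dag):
        stats = effect_trials(asia_dag, "momentum(n)", 10, np.random.default_rng(4))
        assert stats["min"] >= 1.0

    @pytest.mark.parametrize(
        "spec,n,expected",
        [
            ("leaf", 8, ("leaf", 1)),
            ("swap(n/2)", 8, ("swap", 4)),
            ("momentum(2*n)", 8, ("momentum", 16)),
            ("add(n/5)", 8, ("add", 2)),  # round(1.6) -> 2
        ],
    )
    def test_spec_parsing(self, spec, n, expected):
        assert parse_operator_spec(spec, n) == expected

    @pytest.mark.parametrize("bad", ["leaf(x)", "frob", "swap(-1)", "leaf(import os)"])
    def test_bad_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_operator_spec(bad, 8)
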