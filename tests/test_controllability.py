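import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathctrl import (
    DirectedNetwork,
    classify_all,
    classify_node,
    control_nodes,
    gen_random_digraph,
    maximum_matching,
    to_bipartite,
)
from pathctrl.controllability import _IN, _OUT

from _oracles import brute_classify, brute_matching_cardinality, brute_n_d_after_removal


def small_digraphs(max_nodes=8):
    """Hypothesis strategy for small random digraphs (self-loops allowed)."""
    return st.integers(2, max_nodes).flatmap(
        lambda n: st.sets(
            st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)), max_size=n * n
        ).map(
            lambda pairs: DirectedNetwork.from_edges(
                [(f"n{a}", f"n{b}") for a, b in pairs],
                extra_nodes=[f"n{i}" for i in range(n)],
            )
        )
    )


class TestBipartiteMapping:
    def test_edges_connect_out_to_in_copies(self, path_abc):
        bip = to_bipartite(path_abc)
        edges = {frozenset(e) for e in bip.edges}
        assert edges == {
            frozenset({(_OUT, "A"), (_IN, "B")}),
            frozenset({(_OUT, "B"), (_IN, "C")}),
        }

    def test_edgeless_network_has_all_copies_no_edges(self):
        net = DirectedNetwork.from_edges([], extra_nodes=["a", "b", "c"])
        bip = to_bipartite(net)
        assert bip.number_of_nodes() == 6 and bip.number_of_edges() == 0

    def test_self_loop_maps_to_cross_partition_edge(self):
        net = DirectedNetwork.from_edges([("A", "A")])
        bip = to_bipartite(net)
        assert {frozenset(e) for e in bip.edges} == {
            frozenset({(_OUT, "A"), (_IN, "A")})
        }


class TestMaximumMatching:
    def test_path_has_single_driver_at_head(self, path_abc):
        res = maximum_matching(path_abc)
        assert res.cardinality == 2
        assert res.n_d == 1
        assert res.driver_nodes == {"A"}

    def test_out_star_needs_three_drivers(self, out_star):
        res = maximum_matching(out_star)
        assert res.cardinality == 1
        assert res.n_d == 3
        assert len(res.driver_nodes) == 3
        assert "h" in res.driver_nodes  # h's in-copy has no incoming edge

    def test_cycle_is_perfectly_matched(self, three_cycle):
        res = maximum_matching(three_cycle)
        assert res.cardinality == 3
        assert res.driver_nodes == frozenset()
        assert res.n_d == 1  # floor for perfectly matched networks

    def test_matching_is_a_matching(self):
        net = gen_random_digraph(15, 40, seed=2)
        res = maximum_matching(net)
        sources = [u for u, _ in res.matched_edges]
        targets = [v for _, v in res.matched_edges]
        assert len(set(sources)) == len(sources)
        assert len(set(targets)) == len(targets)
        assert len(res.driver_nodes) == net.n_nodes - res.cardinality

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(small_digraphs())
    def test_cardinality_matches_bruteforce(self, net):
        assert maximum_matching(net).cardinality == brute_matching_cardinality(
            net.nodes, net.edges
        )

    def test_n_d_independent_of_iteration_order(self):
        rng = np.random.default_rng(7)
        net = gen_random_digraph(30, 70, seed=1)
        reference = maximum_matching(net).n_d
        edges = list(net.edges)
        for _ in range(20):
            perm = [edges[i] for i in rng.permutation(len(edges))]
            shuffled = DirectedNetwork.from_edges(perm, extra_nodes=net.nodes)
            assert maximum_matching(shuffled).n_d == reference


class TestClassification:
    def test_path_fixture(self, path_abc):
        assert classify_all(path_abc).labels == {
            "A": "neutral", "B": "indispensable", "C": "neutral",
        }

    def test_out_star_fixture(self, out_star):
        labels = classify_all(out_star).labels
        assert labels == {
            "h": "neutral", "a": "dispensable", "b": "dispensable", "c": "dispensable",
        }

    def test_cycle_all_neutral(self, three_cycle):
        assert set(classify_all(three_cycle).labels.values()) == {"neutral"}

    def test_single_node_deletion_labels(self, path_abc):
        assert classify_node(path_abc, "B") == "indispensable"
        assert classify_node(path_abc, "A") == "neutral"

    def test_isolated_node_is_dispensable(self):
        net = DirectedNetwork.from_edges([("A", "B")], extra_nodes=["x"])
        assert classify_node(net, "x") == "dispensable"

    def test_absent_node_raises(self, path_abc):
        with pytest.raises(KeyError):
            classify_node(path_abc, "Z")

    def test_edgeless_network_all_dispensable(self):
        net = DirectedNetwork.from_edges([], extra_nodes=list("abcd"))
        assert control_nodes(net) == frozenset()
        assert set(classify_all(net).labels.values()) == {"dispensable"}

    def test_disjoint_paths_have_two_controls(self):
        net = DirectedNetwork.from_edges(
            [("A", "B"), ("B", "C"), ("X", "Y"), ("Y", "Z")]
        )
        assert control_nodes(net) == {"B", "Y"}

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(small_digraphs(max_nodes=7))
    def test_labels_match_bruteforce_oracle(self, net):
        assert classify_all(net).labels == brute_classify(net.nodes, net.edges)

    def test_incremental_equals_naive_deletion(self):
        """classify_all's incremental re-matching equals copy-and-delete."""
        for seed in range(10):
            net = gen_random_digraph(25, 60, seed=seed)
            cls = classify_all(net)
            for node in sorted(net.nodes)[:8]:
                remnant = net.remove_node(node)
                naive = maximum_matching(remnant).n_d
                assert cls.n_d_removed[node] == naive

    def test_label_counts_partition_nodes(self):
        net = gen_random_digraph(40, 90, seed=4)
        cls = classify_all(net)
        assert len(cls.labels) == net.n_nodes
        total = sum(len(cls.nodes_with_label(l))
                    for l in ("indispensable", "neutral", "dispensable"))
        assert total == net.n_nodes


class TestStructuralInvariants:
    def test_transpose_invariance(self):
        for seed in range(10):
            net = gen_random_digraph(20, 45, seed=seed)
            fwd = classify_all(net)
            rev = classify_all(net.transpose())
            assert fwd.n_d_intact == rev.n_d_intact
            assert fwd.labels == rev.labels

    def test_disjoint_union_additivity(self):
        g = gen_random_digraph(8, 12, seed=1, node_prefix="g")
        h = gen_random_digraph(9, 14, seed=2, node_prefix="h")
        union = DirectedNetwork.from_edges(
            g.edges | h.edges, extra_nodes=g.nodes | h.nodes
        )
        mg, mh, mu = maximum_matching(g), maximum_matching(h), maximum_matching(union)
        assert mu.cardinality == mg.cardinality + mh.cardinality
        # raw driver counts (before the floor) add
        assert (union.n_nodes - mu.cardinality) == (
            (g.n_nodes - mg.cardinality) + (h.n_nodes - mh.cardinality)
        )
        if (g.n_nodes - mg.cardinality) >= 1 and (h.n_nodes - mh.cardinality) >= 1:
            per_component = {**classify_all(g).labels, **classify_all(h).labels}
            assert classify_all(union).labels == per_component
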