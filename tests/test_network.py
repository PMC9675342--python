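import numpy as np
import pytest

from playseq.io_model import PipelineConfig
from playseq.transition_network import (
    NetworkEdge,
    TransitionNetwork,
    build_network,
    community_transition_fractions,
    compare_partitions,
    detect_communities,
    exhaustive_max_modularity,
    modularity,
)
from playseq.transition_stats import TransitionProbabilities, TransitionTestResult
from playseq.preprocess import ElementSequence


def net_from_edges(edges):
    es = tuple(NetworkEdge(a, b, w, 10.0, 0.001) for a, b, w in edges)
    nodes = tuple(sorted({e.source for e in es} | {e.target for e in es}))
    return TransitionNetwork(nodes=nodes, edges=es)


def two_triangle_net():
    edges = [
        ("a", "b", 1.0), ("b", "c", 1.0), ("c", "a", 1.0),
        ("d", "e", 1.0), ("e", "f", 1.0), ("f", "d", 1.0),
        ("c", "d", 1.0),
    ]
    return net_from_edges(edges)


class TestBuildNetwork:
    def _probs(self, els):
        table = {(a,): {b: 0.2 for b in els} for a in els}
        return TransitionProbabilities(1, table)

    def test_directed_edges_and_self_loops(self):
        tests = [
            TransitionTestResult("A", "B", 10, 0.5, 0, 0.0, True),
            TransitionTestResult("B", "A", 8, 0.4, 1, 0.001, True),
            TransitionTestResult("A", "A", 6, 0.1, 0, 0.0, True),
        ]
        net = build_network(tests, self._probs(["A", "B", "C"]))
        assert len(net.edges) == 3
        assert ("A", "B") != ("B", "A")
        assert any(e.source == e.target == "A" for e in net.edges)

    def test_isolates_reported_separately(self):
        tests = [TransitionTestResult("A", "B", 10, 0.5, 0, 0.0, True)]
        net = build_network(tests, self._probs(["A", "B", "C"]))
        assert net.nodes == ("A", "B")
        assert net.isolates == ("C",)

    def test_unfiltered_edges_rejected_with_config(self):
        cfg = PipelineConfig()
        tests = [TransitionTestResult("A", "B", 2, 0.5, 0, 0.0, False)]
        with pytest.raises(ValueError):
            build_network(tests, self._probs(["A", "B"]), cfg)


class TestModularity:
    def test_two_triangle_bridge_closed_form(self):
        net = two_triangle_net()
        mem = {"a": 1, "b": 1, "c": 1, "d": 2, "e": 2, "f": 2}
        # Q = 2 * (3/7 - (7/14)^2) = 5/14
        assert modularity(net, mem) == pytest.approx(5 / 14, abs=1e-12)

    def test_single_community_zero(self):
        net = two_triangle_net()
        mem = {n: 1 for n in net.nodes}
        assert modularity(net, mem) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_two_block_half(self):
        edges = [("a", "b", 1.0), ("c", "d", 1.0)]
        net = net_from_edges(edges)
        mem = {"a": 1, "b": 1, "c": 2, "d": 2}
        assert modularity(net, mem) == pytest.approx(0.5, abs=1e-12)

    def test_self_loops_excluded(self):
        edges = [("a", "b", 1.0), ("a", "a", 5.0)]
        net = net_from_edges(edges)
        assert modularity(net, {"a": 1, "b": 1}) == pytest.approx(0.0, abs=1e-12)

    def test_unknown_node_rejected(self):
        net = two_triangle_net()
        with pytest.raises(ValueError):
            modularity(net, {**{n: 1 for n in net.nodes}, "zz": 2})


class TestDetectCommunities:
    def test_two_triangles_found_exactly(self):
        cfg = PipelineConfig()
        part = detect_communities(two_triangle_net(), cfg)
        assert part.method == "exhaustive"
        assert part.modularity == pytest.approx(5 / 14)
        groups = {}
        for n, c in part.memberships.items():
            groups.setdefault(c, set()).add(n)
        assert set(map(frozenset, groups.values())) == {
            frozenset("abc"),
            frozenset("def"),
        }
        assert part.acceptable  # 0.357 > 0.3

    def test_exhaustive_matches_independent_exact_oracle(self):
        """Cross-check our enumeration against igraph's GLPK-exact optimizer."""
        ig = pytest.importorskip("igraph")
        import networkx as nx

        rng = np.random.default_rng(0)
        for trial in range(10):
            n = int(rng.integers(4, 8))
            g = nx.gnp_random_graph(n, 0.6, seed=int(rng.integers(10**6)))
            if g.number_of_edges() < 2:
                continue
            edges = [
                (f"n{u}", f"n{v}", float(rng.uniform(0.1, 1.0))) for u, v in g.edges()
            ]
            net = net_from_edges(edges)
            _, q = exhaustive_max_modularity(net)
            G = ig.Graph()
            G.add_vertices(list(net.nodes))
            nodes = list(net.nodes)
            ws = []
            for e in net.edges:
                G.add_edge(nodes.index(e.source), nodes.index(e.target))
                ws.append(e.weight)
            ref = G.community_optimal_modularity(weights=ws)
            assert q == pytest.approx(ref.modularity, abs=1e-9)

    def test_fallback_used_above_exact_limit(self):
        cfg = PipelineConfig(exact_community_limit=4)
        part = detect_communities(two_triangle_net(), cfg, np.random.default_rng(0))
        assert part.method == "louvain_refined"
        assert part.modularity == pytest.approx(5 / 14)


class TestFractions:
    def _seqs(self, tokens_list):
        return [ElementSequence("b", "p", tuple(t)) for t in tokens_list]

    def test_all_one_community_ratio_one(self, rng):
        seqs = self._seqs([["A", "B", "A", "B", "C"]])
        mem = {"A": 1, "B": 1, "C": 1}
        obs, exp, ratio = community_transition_fractions(seqs, mem, 50, rng)
        assert obs == exp == 1.0
        assert ratio == 1.0

    def test_block_structure_inflates_ratio(self, rng):
        seqs = self._seqs([["A", "B"] * 20 + ["C", "D"] * 20])
        mem = {"A": 1, "B": 1, "C": 2, "D": 2}
        obs, exp, ratio = community_transition_fractions(seqs, mem, 200, rng)
        assert obs > 0.9
        assert ratio > 1.5

    def test_no_transitions_rejected(self, rng):
        seqs = self._seqs([["X", "Y"]])
        with pytest.raises(ValueError):
            community_transition_fractions(seqs, {"A": 1, "B": 2}, 10, rng)


class TestComparePartitions:
    def test_identical_partitions_ari_one(self):
        a = {"x": 1, "y": 1, "z": 2}
        ari, nmi, table = compare_partitions(a, dict(a))
        assert ari == pytest.approx(1.0)
        assert nmi == pytest.approx(1.0)

    def test_singletons_vs_one_block_chance_level(self):
        a = {f"e{i}": i for i in range(6)}
        b = {f"e{i}": 1 for i in range(6)}
        ari, _, _ = compare_partitions(a, b)
        assert ari == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_element_sets_rejected(self):
        with pytest.raises(ValueError):
            compare_partitions({"a": 1}, {"b": 1})
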