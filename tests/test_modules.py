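"""Edge betweenness and Girvan-Newman module extraction.

Betweenness is checked against a brute-force all-pairs shortest-path
count; community recovery is checked on planted-partition graphs.
"""

import itertools

import networkx as nx
import pandas as pd
import pytest

from cerna_scope.io import DrugTargetTable
from cerna_scope.modules import (
    edge_betweenness,
    girvan_newman_partition,
    module_drug_overlay,
    module_to_graph,
)


def brute_force_edge_betweenness(graph: nx.Graph) -> dict:
    """Sum, over unordered node pairs, the fraction of shortest paths
    crossing each edge — by explicit path enumeration."""
    scores = {tuple(sorted(e)): 0.0 for e in graph.edges}
    for s, t in itertools.combinations(sorted(graph.nodes), 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for u, v in zip(path, path[1:]):
                scores[tuple(sorted((u, v)))] += 1.0 / len(paths)
    return scores


def _typed(graph: nx.Graph) -> nx.Graph:
    """Give a plain test graph valid miRNA/mRNA typing (bipartite-safe
    labels are irrelevant to clustering, which ignores types)."""
    g = nx.Graph()
    for n in graph.nodes:
        g.add_node(str(n), node_type="mRNA")
    for u, v in graph.edges:
        g.add_edge(str(u), str(v), edge_type="mirna_mrna")
    return g


class TestEdgeBetweenness:
    def test_bridge_between_triangles_dominates(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
        g.add_edges_from([("x", "y"), ("y", "z"), ("x", "z")])
        g.add_edge("c", "x")
        scores = edge_betweenness(g)
        assert max(scores, key=scores.get) == ("c", "x")

    def test_triangle_is_symmetric(self):
        g = nx.complete_graph(3)
        scores = edge_betweenness(g)
        assert len(set(round(s, 9) for s in scores.values())) == 1

    def test_path_graph_middle_edge_score(self):
        g = nx.path_graph(4)  # 0-1-2-3
        scores = edge_betweenness(g)
        brute = brute_force_edge_betweenness(g)
        assert brute[(1, 2)] == pytest.approx(4.0)  # pairs (0,2),(0,3),(1,2),(1,3)
        for e, v in brute.items():
            assert scores[e] == pytest.approx(v)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_small_random_graphs(self, seed):
        g = nx.gnp_random_graph(8, 0.4, seed=seed)
        scores = edge_betweenness(g) if g.number_of_edges() else {}
        brute = brute_force_edge_betweenness(g)
        for e, v in brute.items():
            assert scores[e] == pytest.approx(v, abs=1e-9)

    @pytest.mark.parametrize(
        "graph",
        [nx.cycle_graph(6), nx.star_graph(5), nx.complete_bipartite_graph(3, 4),
         nx.barbell_graph(4, 1)],
        ids=["cycle", "star", "bipartite", "barbell"],
    )
    def test_matches_brute_force_on_structured_graphs(self, graph):
        scores = edge_betweenness(graph)
        for e, v in brute_force_edge_betweenness(graph).items():
            assert scores[e] == pytest.approx(v, abs=1e-9)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            edge_betweenness(nx.Graph())


class TestGirvanNewman:
    def test_two_cliques_one_bridge_split_exactly(self):
        g = nx.Graph()
        for offset in (0, 4):
            for u, v in itertools.combinations(range(offset, offset + 4), 2):
                g.add_edge(u, v)
        g.add_edge(0, 4)
        modules, q = girvan_newman_partition(_typed(g))
        assert len(modules) == 2
        groups = sorted(sorted(int(n) for n in m.nodes) for m in modules)
        assert groups == [[0, 1, 2, 3], [4, 5, 6, 7]]
        assert q > 0

    def test_single_clique_stays_whole(self):
        modules, q = girvan_newman_partition(_typed(nx.complete_graph(5)))
        assert len(modules) == 1
        assert modules[0].size == 5
        assert q == pytest.approx(0.0)

    def test_small_components_are_hidden(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (2, 0)])  # triangle
        g.add_edge(10, 11)  # dyad, below min_size
        modules, _ = girvan_newman_partition(_typed(g), min_size=3)
        assert len(modules) == 1
        assert modules[0].size == 3

    def test_modules_are_node_disjoint_and_within_network(self, small_study):
        from cerna_scope.network import build_network
        from test_network import _candidate

        cands = [
            _candidate(t.lncrna, t.mrna, t.mirnas)
            for t in small_study.truth.planted_triplets
        ]
        net = build_network(cands)
        modules, q = girvan_newman_partition(net)
        seen = set()
        for mod in modules:
            assert not (seen & set(mod.nodes))
            seen |= set(mod.nodes)
        assert seen <= set(net.nodes)
        assert all(m.size >= 3 for m in modules)
        assert q >= 0.0

    def test_undersized_network_returns_no_modules(self):
        g = _typed(nx.path_graph(2))
        modules, q = girvan_newman_partition(g, min_size=3)
        assert modules == [] and q == 0.0

    def test_planted_partition_recovered(self, small_study):
        """Communities planted in the interaction structure are recovered
        (adjusted Rand >= 0.9 against the planted labels)."""
        from sklearn.metrics import adjusted_rand_score

        from cerna_scope.network import build_network
        from test_network import _candidate

        truth = small_study.truth
        cands = [
            _candidate(t.lncrna, t.mrna, t.mirnas) for t in truth.planted_triplets
        ]
        net = build_network(cands)
        modules, _ = girvan_newman_partition(net)
        predicted = {n: m.module_id for m in modules for n in m.nodes}
        common = sorted(set(predicted) & set(truth.planted_module_partition))
        assert len(common) >= 0.9 * net.number_of_nodes()
        ari = adjusted_rand_score(
            [truth.planted_module_partition[n] for n in common],
            [predicted[n] for n in common],
        )
        assert ari >= 0.9


class TestDrugOverlayOnModules:
    def test_drugs_attach_only_to_module_mrnas(self):
        g = nx.Graph()
        g.add_node("L1", node_type="lncRNA")
        g.add_node("M1", node_type="miRNA")
        g.add_node("G1", node_type="mRNA")
        g.add_edge("M1", "L1", edge_type="mirna_lncrna")
        g.add_edge("M1", "G1", edge_type="mirna_mrna")
        modules, _ = girvan_newman_partition(g)
        drugs = DrugTargetTable(
            edges=pd.DataFrame(
                [("D1", "G1"), ("D2", "ELSEWHERE")], columns=["drug", "target"]
            )
        )
        out = module_drug_overlay(modules, drugs)
        assert out[0].nodes["D1"] == "drug"
        assert "D2" not in out[0].nodes
        assert out[0].drug_edges == [("D1", "G1")]

    def test_module_to_graph_round_trip(self):
        g = nx.Graph()
        g.add_node("M1", node_type="miRNA")
        g.add_node("G1", node_type="mRNA")
        g.add_node("G2", node_type="mRNA")
        g.add_edge("M1", "G1", edge_type="mirna_mrna")
        g.add_edge("M1", "G2", edge_type="mirna_mrna")
        modules, _ = girvan_newman_partition(g)
        back = module_to_graph(modules[0])
        assert nx.utils.graphs_equal(back, g)
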