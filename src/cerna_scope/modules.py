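"""Module extraction by edge-betweenness (Girvan–Newman) clustering.

Edges with the highest shortest-path betweenness are removed one at a
time (ties broken by lexicographic edge order, for determinism), the
betweenness recomputed, and the partition into connected components
tracked.  The partition maximising Newman modularity Q on the original
graph is returned; components smaller than ``min_size`` (default 3) are
then hidden from the module list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
from networkx.algorithms.community import modularity as nx_modularity

from cerna_scope.io import DrugTargetTable

logger = logging.getLogger(__name__)


@dataclass
class Module:
    """A connected node subset extracted from the network."""

    module_id: int
    nodes: dict[str, str]  # node id -> node_type
    edges: list[tuple[str, str, str]]  # (u, v, edge_type), induced
    modularity_contribution: float = 0.0
    drug_edges: list[tuple[str, str]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.nodes)


def edge_betweenness(network: nx.Graph) -> dict[tuple[str, str], float]:
    """Shortest-path edge betweenness (unweighted, unnormalised: each
    unordered node pair counts once), keyed by sorted edge tuple."""
    if network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    raw = nx.edge_betweenness_centrality(network, normalized=False)
    return {tuple(sorted((u, v))): score for (u, v), score in raw.items()}


def _partition_of(graph: nx.Graph) -> list[frozenset[str]]:
    return sorted(
        (frozenset(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), min(c)),
    )


def girvan_newman_partition(
    network: nx.Graph, min_size: int = 3
) -> tuple[list[Module], float]:
    """Girvan–Newman clustering with modularity-based cut selection.

    Returns (modules, Q) where Q is the modularity of the selected
    partition on the original graph and ``modules`` are its components of
    size >= min_size, ordered by size descending.  The trivial
    all-in-one-component partition competes on equal terms, so a graph
    that no split improves (e.g. a clique) comes back as one module.
    """
    if network.number_of_nodes() < min_size:
        logger.warning(
            "network has %d nodes (< min_size=%d); no modules returned",
            network.number_of_nodes(), min_size,
        )
        return [], 0.0

    work = network.copy()
    best_partition = _partition_of(work)
    best_q = nx_modularity(network, best_partition) if network.number_of_edges() else 0.0

    while work.number_of_edges() > 0:
        scores = edge_betweenness(work)
        top = max(scores.values())
        edge = min(e for e, s in scores.items() if s == top)
        work.remove_edge(*edge)
        partition = _partition_of(work)
        q = nx_modularity(network, partition)
        if q > best_q + 1e-12:
            best_q = q
            best_partition = partition

    modules: list[Module] = []
    mid = 0
    for comp in best_partition:
        if len(comp) < min_size:
            continue
        mid += 1
        sub = network.subgraph(comp)
        modules.append(
            Module(
                module_id=mid,
                nodes={n: network.nodes[n]["node_type"] for n in sorted(comp)},
                edges=[
                    (u, v, d["edge_type"])
                    for u, v, d in (
                        (min(a, b), max(a, b), data)
                        for a, b, data in sub.edges(data=True)
                    )
                ],
                modularity_contribution=_community_q_term(network, comp),
            )
        )
    logger.info(
        "girvan-newman: %d modules (>= %d nodes) at Q=%.4f from %d components",
        len(modules), min_size, best_q, len(best_partition),
    )
    return modules, float(best_q)


def _community_q_term(graph: nx.Graph, community: frozenset[str]) -> float:
    """One community's additive term of Newman modularity."""
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    within = sum(1 for u, v in graph.edges if u in community and v in community)
    deg_sum = sum(d for _, d in graph.degree(community))
    return within / m - (deg_sum / (2 * m)) ** 2


def module_drug_overlay(
    modules: list[Module], drugs: DrugTargetTable
) -> list[Module]:
    """Attach, per module, the drugs targeting any of its mRNA nodes."""
    out = []
    for mod in modules:
        mrnas = {n for n, t in mod.nodes.items() if t == "mRNA"}
        drug_edges = sorted(
            (row.drug, row.target)
            for row in drugs.edges.itertuples(index=False)
            if row.target in mrnas
        )
        nodes = dict(mod.nodes)
        for drug, _ in drug_edges:
            nodes[drug] = "drug"
        out.append(
            Module(
                module_id=mod.module_id,
                nodes=nodes,
                edges=mod.edges + [(d, t, "drug_target") for d, t in drug_edges],
                modularity_contribution=mod.modularity_contribution,
                drug_edges=drug_edges,
            )
        )
    return out


def module_to_graph(module: Module) -> nx.Graph:
    """Materialise one module as a typed graph (for export)."""
    g = nx.Graph()
    for node, node_type in module.nodes.items():
        g.add_node(node, node_type=node_type)
    for u, v, edge_type in module.edges:
        g.add_edge(u, v, edge_type=edge_type)
    return g
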