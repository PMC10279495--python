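"""Typed lncRNA-miRNA-mRNA network assembly with a drug-target overlay.

The network is an undirected :class:`networkx.Graph` whose nodes carry a
``node_type`` attribute (lncRNA, miRNA, mRNA, drug) and whose edges carry
an ``edge_type`` (mirna_lncrna, mirna_mrna, drug_target).  Only three
edge types exist: the lncRNA-mRNA ceRNA pairing itself lives in the
candidate table, not in the graph — the graph records the regulator
relations the pairing was inferred from, plus drugs attached to their
target mRNAs.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from cerna_scope.cerna import CeRNACandidate
from cerna_scope.io import DrugTargetTable

logger = logging.getLogger(__name__)

_ALLOWED = {
    frozenset(("miRNA", "lncRNA")): "mirna_lncrna",
    frozenset(("miRNA", "mRNA")): "mirna_mrna",
    frozenset(("drug", "mRNA")): "drug_target",
}


def validate_network(network: nx.Graph) -> None:
    """Assert the type invariants: known node types, allowed edge-type
    pairings, no self-loops."""
    for node, data in network.nodes(data=True):
        if data.get("node_type") not in ("lncRNA", "miRNA", "mRNA", "drug"):
            raise ValueError(f"node {node!r} has invalid node_type {data.get('node_type')!r}")
    for u, v, data in network.edges(data=True):
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        pair = frozenset((network.nodes[u]["node_type"], network.nodes[v]["node_type"]))
        expected = _ALLOWED.get(pair)
        if expected is None:
            raise ValueError(f"edge {u!r}-{v!r} joins disallowed types {sorted(pair)}")
        if data.get("edge_type") != expected:
            raise ValueError(
                f"edge {u!r}-{v!r} has edge_type {data.get('edge_type')!r}, "
                f"expected {expected!r}"
            )


def build_network(accepted: list[CeRNACandidate]) -> nx.Graph:
    """Build the ceRNA network from accepted candidates.

    For every accepted pair and every shared miRNA s, add the edges
    s-lncRNA and s-mRNA.  Nodes appear only when incident to at least one
    edge; duplicate edges collapse.
    """
    g = nx.Graph()
    for cand in accepted:
        if not cand.accepted:
            continue
        for mir in sorted(cand.shared_mirna_ids):
            g.add_node(cand.lncrna_id, node_type="lncRNA")
            g.add_node(cand.mrna_id, node_type="mRNA")
            g.add_node(mir, node_type="miRNA")
            g.add_edge(mir, cand.lncrna_id, edge_type="mirna_lncrna")
            g.add_edge(mir, cand.mrna_id, edge_type="mirna_mrna")
    validate_network(g)
    logger.info("built ceRNA network: %s", node_type_counts(g))
    return g


def annotate_drugs(network: nx.Graph, drugs: DrugTargetTable) -> nx.Graph:
    """Overlay drug-target edges: a drug is added iff it targets at least
    one mRNA node already in the network."""
    g = network.copy()
    mrnas = {n for n, d in g.nodes(data=True) if d["node_type"] == "mRNA"}
    added = 0
    for row in drugs.edges.itertuples(index=False):
        if row.target in mrnas:
            g.add_node(row.drug, node_type="drug")
            g.add_edge(row.drug, row.target, edge_type="drug_target")
            added += 1
    validate_network(g)
    logger.info("drug overlay: %d drug_target edges added", added)
    return g


def degree_report(network: nx.Graph) -> pd.DataFrame:
    """Table of (node, node_type, degree) sorted by degree descending,
    ties broken lexicographically by id."""
    rows = [
        {"node": n, "node_type": network.nodes[n]["node_type"], "degree": d}
        for n, d in network.degree()
    ]
    df = pd.DataFrame(rows, columns=["node", "node_type", "degree"])
    return df.sort_values(
        ["degree", "node"], ascending=[False, True]
    ).reset_index(drop=True)


def node_type_counts(network: nx.Graph) -> dict[str, int]:
    counts = {t: 0 for t in ("lncRNA", "miRNA", "mRNA", "drug")}
    for _, data in network.nodes(data=True):
        counts[data["node_type"]] += 1
    counts["total"] = network.number_of_nodes()
    return counts


def edge_type_counts(network: nx.Graph) -> dict[str, int]:
    counts = {t: 0 for t in ("mirna_lncrna", "mirna_mrna", "drug_target")}
    for _, _, data in network.edges(data=True):
        counts[data["edge_type"]] += 1
    counts["total"] = network.number_of_edges()
    return counts
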