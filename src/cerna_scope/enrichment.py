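"""Hypergeometric over-representation analysis against GMT term sets.

Shares its tail kernel with the shared-miRNA test: for a query of
n_query genes drawn from a universe of N genes, a term annotating K of
them, and k query genes in the term, the p-value is
P(X >= k) with X ~ Hypergeometric(N, K, n_query).  Terms with k = 0 are
skipped; BH adjustment runs across all tested terms.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from cerna_scope.cerna import hypergeom_upper_tail
from cerna_scope.diffexpr import bh_adjust
from cerna_scope.io import AnnotationSets

logger = logging.getLogger(__name__)


def enrich(
    query: set[str],
    annotations: AnnotationSets,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Over-representation of ``query`` in every annotation term.

    The universe defaults to the annotation collection's explicit
    universe if set, else the union of all its gene sets.  Query genes
    outside the universe are dropped with a warning.  Returns a frame
    sorted by FDR ascending with columns term_id, term_name, k, K,
    n_query, N_universe, p_value, fdr, score (-log10 FDR) and genes.
    """
    if universe is None:
        universe = set(annotations.universe or annotations.all_genes())
    universe = set(universe)
    if not query:
        logger.warning("empty query gene set; empty enrichment table")
        return _empty_frame()
    stray = set(query) - universe
    if stray:
        logger.warning(
            "%d query gene(s) absent from universe dropped (e.g. %s)",
            len(stray), sorted(stray)[0],
        )
    query_in = set(query) & universe
    if not query_in:
        return _empty_frame()

    N, n_query = len(universe), len(query_in)
    rows = []
    for term, genes in annotations.sets.items():
        genes_in = genes & universe
        hits = sorted(query_in & genes_in)
        k, K = len(hits), len(genes_in)
        if k == 0 or K == 0:
            continue
        p = hypergeom_upper_tail(k, N, K, n_query)
        rows.append(
            {
                "term_id": term,
                "term_name": annotations.names.get(term, term),
                "k": k,
                "K": K,
                "n_query": n_query,
                "N_universe": N,
                "p_value": p,
                "genes": ",".join(hits),
            }
        )
    if not rows:
        return _empty_frame()
    df = pd.DataFrame(rows)
    df["fdr"] = bh_adjust(df["p_value"])
    with np.errstate(divide="ignore"):
        df["score"] = -np.log10(df["fdr"].to_numpy())
    df = df.sort_values(["fdr", "p_value", "term_id"]).reset_index(drop=True)
    cols = [
        "term_id", "term_name", "k", "K", "n_query", "N_universe",
        "p_value", "fdr", "score", "genes",
    ]
    return df[cols]


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "term_id", "term_name", "k", "K", "n_query", "N_universe",
            "p_value", "fdr", "score", "genes",
        ]
    )
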