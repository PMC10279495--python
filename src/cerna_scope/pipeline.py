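"""One-command orchestration: simulate/load -> DE -> ceRNA -> network ->
modules -> enrichment, with a manifest recording every stage count.

The manifest is a JSON document whose content depends only on the input
data and configuration (no timestamps), so identical config + seed give
byte-identical manifests.  It also performs the bookkeeping the study
report performs: rounded DE percentages and per-type node counts that
must sum to the network total.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from cerna_scope.cerna import (
    candidates_to_frame,
    coexpression_filter,
    enumerate_candidates,
)
from cerna_scope.diffexpr import differential_expression
from cerna_scope.enrichment import enrich
from cerna_scope.io import (
    read_annotation_gmt,
    read_drug_target_table,
    read_expression_matrix,
    read_interaction_table,
    write_network,
)
from cerna_scope.modules import (
    girvan_newman_partition,
    module_drug_overlay,
    module_to_graph,
)
from cerna_scope.network import (
    annotate_drugs,
    build_network,
    edge_type_counts,
    node_type_counts,
)
from cerna_scope.synthetic import SimulationConfig, simulate_all, write_fixtures

logger = logging.getLogger(__name__)


def percent_rounded(k: int, total: int) -> int:
    """Share of ``k`` in ``total`` as a whole percentage (round half up)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(k / total * 100 + 0.5)


@dataclass
class PipelineConfig:
    """Everything one run needs.

    Either ``simulate`` is true (a synthetic study is generated from
    ``sim``) or the input paths must all be set.  The coexpression mode
    defaults to ``case_only``: the study design targets coexpression
    gained in disease, which the control group cannot corroborate.
    """

    outdir: str = "cerna_run"
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    expression_path: str | None = None
    metadata_path: str | None = None
    mirna_mrna_path: str | None = None
    mirna_lncrna_path: str | None = None
    drugs_path: str | None = None
    gmt_path: str | None = None
    alpha: float = 0.05
    fc_cutoff: float | None = None
    coexpression_mode: str = "case_only"
    r_threshold: float = 0.5
    p_threshold: float = 0.05
    universe_mode: str = "union"
    universe_size: int | None = None
    min_module_size: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name, val in (("alpha", self.alpha), ("p_threshold", self.p_threshold)):
            if not (0.0 < val <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {val}")
        if not (-1.0 <= self.r_threshold <= 1.0):
            raise ValueError("r_threshold must lie in [-1, 1]")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if not self.simulate:
            needed = [
                self.expression_path, self.metadata_path,
                self.mirna_mrna_path, self.mirna_lncrna_path,
            ]
            if any(p is None for p in needed):
                raise ValueError(
                    "without simulate=True, expression/metadata/interaction "
                    "paths are all required"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        cfg = cls(sim=sim, **raw)
        if "seed" in raw:
            cfg.sim.seed = cfg.seed
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk).

    Writes under ``config.outdir``: the input fixtures (when simulated),
    the DE table, the candidate table, the network (GraphML + SIF), one
    GraphML + node TSV per module, a module summary, enrichment tables
    and ``manifest.json``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ---- inputs -------------------------------------------------------
        stage = "inputs"
        truth = None
        if config.simulate:
            config.sim.seed = config.seed
            study = simulate_all(config.sim)
            write_fixtures(study, outdir / "inputs")
            expr = study.expression
            mirna_mrna, mirna_lncrna = study.mirna_mrna, study.mirna_lncrna
            drugs, annotations = study.drugs, study.annotations
            truth = study.truth
        else:
            expr = read_expression_matrix(config.expression_path, config.metadata_path)
            mirna_mrna = read_interaction_table(config.mirna_mrna_path, "mRNA")
            mirna_lncrna = read_interaction_table(config.mirna_lncrna_path, "lncRNA")
            drugs = (
                read_drug_target_table(config.drugs_path) if config.drugs_path else None
            )
            annotations = read_annotation_gmt(config.gmt_path) if config.gmt_path else None

        # ---- differential expression -------------------------------------
        stage = "differential_expression"
        de = differential_expression(expr, alpha=config.alpha, fc_cutoff=config.fc_cutoff)
        de.to_csv(outdir / "differential_expression.tsv", sep="\t")
        degs = set(de.index[(de["is_significant"]) & (de["kind"] == "gene")])
        dels = set(de.index[(de["is_significant"]) & (de["kind"] == "lncRNA")])

        # ---- ceRNA inference ----------------------------------------------
        stage = "cerna_inference"
        candidates = enumerate_candidates(
            dels, degs, mirna_mrna, mirna_lncrna,
            universe_mode=config.universe_mode, universe_size=config.universe_size,
        )
        candidates = coexpression_filter(
            candidates, expr,
            mode=config.coexpression_mode,
            r_threshold=config.r_threshold,
            p_threshold=config.p_threshold,
            alpha=config.alpha,
        )
        candidates_to_frame(candidates).to_csv(
            outdir / "cerna_candidates.tsv", sep="\t", index=False
        )
        accepted = [c for c in candidates if c.accepted]

        # ---- network ------------------------------------------------------
        stage = "network_build"
        net = build_network(accepted)
        if drugs is not None:
            net = annotate_drugs(net, drugs)
        write_network(net, outdir / "network.graphml", "graphml")
        write_network(net, outdir / "network.sif", "sif")

        # ---- modules ------------------------------------------------------
        stage = "module_detection"
        # modules are cut on the RNA-only graph; drugs are overlaid after
        rna_net = net.subgraph(
            [n for n, d in net.nodes(data=True) if d["node_type"] != "drug"]
        ).copy()
        modules, q = girvan_newman_partition(rna_net, min_size=config.min_module_size)
        if drugs is not None:
            modules = module_drug_overlay(modules, drugs)
        mod_dir = outdir / "modules"
        mod_dir.mkdir(exist_ok=True)
        summary_rows = []
        for mod in modules:
            write_network(
                module_to_graph(mod), mod_dir / f"module{mod.module_id}.graphml"
            )
            with open(mod_dir / f"module{mod.module_id}_nodes.tsv", "w") as fh:
                fh.write("node\tnode_type\n")
                for node in sorted(mod.nodes):
                    fh.write(f"{node}\t{mod.nodes[node]}\n")
            counts = {"lncRNA": 0, "miRNA": 0, "mRNA": 0, "drug": 0}
            for t in mod.nodes.values():
                counts[t] += 1
            summary_rows.append(
                {"module_id": mod.module_id, "size": mod.size, **counts}
            )
        with open(mod_dir / "summary.tsv", "w") as fh:
            fh.write("module_id\tsize\tlncRNA\tmiRNA\tmRNA\tdrug\n")
            for row in summary_rows:
                fh.write(
                    f"{row['module_id']}\t{row['size']}\t{row['lncRNA']}\t"
                    f"{row['miRNA']}\t{row['mRNA']}\t{row['drug']}\n"
                )

        # ---- enrichment ---------------------------------------------------
        stage = "enrichment"
        enrichment_summary = {}
        if annotations is not None:
            net_genes = {
                n for n, d in net.nodes(data=True) if d["node_type"] == "mRNA"
            }
            table = enrich(net_genes, annotations)
            table.to_csv(outdir / "enrichment_network.tsv", sep="\t", index=False)
            enrichment_summary["network"] = {
                "tested_terms": int(len(table)),
                "significant_terms": int((table["fdr"] < config.alpha).sum()),
                "top_term": str(table["term_id"].iloc[0]) if len(table) else None,
            }
            for mod in modules:
                mod_genes = {n for n, t in mod.nodes.items() if t == "mRNA"}
                mtab = enrich(mod_genes, annotations)
                mtab.to_csv(
                    outdir / f"enrichment_module{mod.module_id}.tsv",
                    sep="\t", index=False,
                )
                enrichment_summary[f"module{mod.module_id}"] = {
                    "tested_terms": int(len(mtab)),
                    "significant_terms": int((mtab["fdr"] < config.alpha).sum()),
                    "top_term": str(mtab["term_id"].iloc[0]) if len(mtab) else None,
                }

        # ---- manifest -----------------------------------------------------
        stage = "manifest"
        n_genes = int((de["kind"] == "gene").sum())
        n_lncrnas = int((de["kind"] == "lncRNA").sum())
        node_counts = node_type_counts(net)
        from cerna_scope import __version__ as pkg_version

        manifest = {
            "version": pkg_version,
            "seed": config.seed,
            "parameters": {
                "alpha": config.alpha,
                "fc_cutoff": config.fc_cutoff,
                "coexpression_mode": config.coexpression_mode,
                "r_threshold": config.r_threshold,
                "p_threshold": config.p_threshold,
                "universe_mode": config.universe_mode,
                "min_module_size": config.min_module_size,
                "simulate": config.simulate,
                "sim": dataclasses.asdict(config.sim) if config.simulate else None,
            },
            "counts": {
                "features_gene": n_genes,
                "features_lncrna": n_lncrnas,
                "degs": len(degs),
                "dels": len(dels),
                "deg_percent": percent_rounded(len(degs), n_genes),
                "del_percent": percent_rounded(len(dels), n_lncrnas),
                "candidate_pairs": len(candidates),
                "accepted_pairs": len(accepted),
                "nodes": node_counts,
                "edges": edge_type_counts(net),
                "modules": len(modules),
                "module_sizes": [m.size for m in modules],
                "modularity": q,
            },
            "enrichment": enrichment_summary,
        }
        assert manifest["counts"]["accepted_pairs"] <= manifest["counts"]["candidate_pairs"]
        assert sum(
            v for k, v in node_counts.items() if k != "total"
        ) == node_counts["total"]

        if truth is not None:
            accepted_pairs = {(c.lncrna_id, c.mrna_id) for c in accepted}
            planted = truth.triplet_pairs
            tp = len(accepted_pairs & planted)
            manifest["truth_evaluation"] = {
                "planted_triplets": len(planted),
                "true_positives": tp,
                "recall": tp / len(planted) if planted else None,
                "precision": tp / len(accepted_pairs) if accepted_pairs else None,
                "negative_correlated_accepted": len(
                    accepted_pairs & set(truth.negative_correlated)
                ),
                "negative_shared_accepted": len(
                    accepted_pairs
                    & {(t.lncrna, t.mrna) for t in truth.negative_shared}
                ),
            }

        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
        logger.info("pipeline complete: %s", outdir / "manifest.json")
        return manifest
    except Exception as exc:
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
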