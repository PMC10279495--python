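"""Synthetic study generator with planted ground truth.

Emulates a small unbalanced two-group blood-exosome RNA-seq design
(6 case vs 32 control by default) on the TPM scale, together with
miRNA-target interaction tables, a drug-target table and a GMT term
collection, all carrying planted signal:

* a fixed fraction of genes and lncRNAs is differentially expressed
  (floor(n x fraction), a +/- shift of ``de_log_fc`` on the log scale in
  the case group);
* ``n_planted_triplets`` lncRNA-mRNA pairs (drawn from the DE features)
  share ``shared_mirnas_per_triplet`` miRNA regulators and gain
  coexpression in the case group through a shared latent factor — the
  factor loading is set so the population case-group Pearson correlation
  equals ``planted_correlation``;
* triplets are grouped into ``n_communities`` blocks that draw their
  shared miRNAs from disjoint per-community pools, planting a community
  structure in the resulting network;
* negative controls: pairs that gain case coexpression but share no
  miRNA, and pairs that share miRNAs but are uncorrelated;
* one "signal" annotation term collects the planted-triplet mRNAs;
* drugs preferentially target planted-triplet mRNAs.

Every generator is deterministic for a fixed seed; each stage consumes
an independent substream derived from the single config seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cerna_scope.io import (
    AnnotationSets,
    DrugTargetTable,
    ExpressionMatrix,
    InteractionTable,
    write_annotation_gmt,
    write_drug_target_table,
    write_expression_matrix,
    write_interaction_table,
)

_STREAM = {"expression": 0, "interactions": 1, "drugs": 2, "annotations": 3}


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic generator.

    Defaults model a small unbalanced exosome RNA-seq cohort: 6 case and
    32 control samples, 15% of genes and 12% of lncRNAs differentially
    expressed.  ``de_log_fc`` is a natural-log shift (1.5 ~ 4.5-fold);
    ``planted_correlation`` is the population case-group Pearson r of
    planted pairs, set high (0.97) because a correlation test with only
    6 case samples needs sample r > 0.81 for p < 0.05.
    """

    n_genes: int = 2000
    n_lncrnas: int = 300
    n_mirnas: int = 150
    n_case: int = 6
    n_control: int = 32
    de_fraction_genes: float = 0.15
    de_fraction_lncrnas: float = 0.12
    de_log_fc: float = 1.5
    noise_sd: float = 0.5
    n_planted_triplets: int = 20
    shared_mirnas_per_triplet: int = 4
    planted_correlation: float = 0.97
    n_communities: int = 4
    community_pool_extra: int = 2  # pool size = shared_mirnas_per_triplet + extra
    n_negative_correlated: int = 5
    n_negative_shared: int = 5
    background_edge_prob: float = 0.005
    n_drugs: int = 30
    targets_per_drug: int = 5
    n_terms: int = 50
    genes_per_term: int = 20
    baseline_log_range: tuple[float, float] = (1.0, 6.0)
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes, "n_lncrnas": self.n_lncrnas,
            "n_mirnas": self.n_mirnas,
            "shared_mirnas_per_triplet": self.shared_mirnas_per_triplet,
            "n_communities": self.n_communities, "n_drugs": self.n_drugs,
            "targets_per_drug": self.targets_per_drug, "n_terms": self.n_terms,
            "genes_per_term": self.genes_per_term,
        }
        for name, val in counts.items():
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        # zero planted signal is a valid (null) study design
        for name, val in (
            ("n_planted_triplets", self.n_planted_triplets),
            ("n_negative_correlated", self.n_negative_correlated),
            ("n_negative_shared", self.n_negative_shared),
        ):
            if val < 0:
                raise ValueError(f"{name} must be non-negative, got {val}")
        for name, val in (
            ("de_fraction_genes", self.de_fraction_genes),
            ("de_fraction_lncrnas", self.de_fraction_lncrnas),
        ):
            if not (0.0 <= val < 1.0):
                raise ValueError(f"{name} must lie in [0, 1), got {val}")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        if not (0.0 < self.planted_correlation < 1.0):
            raise ValueError("planted_correlation must lie in (0, 1)")
        if not (0.0 <= self.background_edge_prob < 1.0):
            raise ValueError("background_edge_prob must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        n_pairs = (
            self.n_planted_triplets
            + self.n_negative_correlated
            + self.n_negative_shared
        )
        if n_pairs > math.floor(self.n_lncrnas * self.de_fraction_lncrnas):
            raise ValueError("not enough DE lncRNAs to host planted/negative pairs")
        if n_pairs > math.floor(self.n_genes * self.de_fraction_genes):
            raise ValueError("not enough DE genes to host planted/negative pairs")
        pool = self.shared_mirnas_per_triplet + self.community_pool_extra
        if self.n_communities * pool + 4 * self.n_negative_correlated > self.n_mirnas:
            raise ValueError("n_mirnas too small for community pools and controls")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([abs(int(self.seed)) % (2**31), _STREAM[stage]])


@dataclass
class Triplet:
    lncrna: str
    mrna: str
    mirnas: frozenset[str]


@dataclass
class GroundTruth:
    """Planted signal: what the pipeline is supposed to recover."""

    de_genes: dict[str, int]  # id -> direction (+1 up in case, -1 down)
    de_lncrnas: dict[str, int]
    planted_triplets: list[Triplet]
    negative_correlated: list[tuple[str, str]]  # coexpressed, no shared miRNA
    negative_shared: list[Triplet]  # shared miRNAs, not coexpressed
    planted_module_partition: dict[str, int]

    @property
    def triplet_pairs(self) -> set[tuple[str, str]]:
        return {(t.lncrna, t.mrna) for t in self.planted_triplets}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_genes": self.de_genes,
            "de_lncrnas": self.de_lncrnas,
            "planted_triplets": [
                {"lncrna": t.lncrna, "mrna": t.mrna, "mirnas": sorted(t.mirnas)}
                for t in self.planted_triplets
            ],
            "negative_correlated": [list(p) for p in self.negative_correlated],
            "negative_shared": [
                {"lncrna": t.lncrna, "mrna": t.mrna, "mirnas": sorted(t.mirnas)}
                for t in self.negative_shared
            ],
            "planted_module_partition": self.planted_module_partition,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            de_genes={k: int(v) for k, v in d["de_genes"].items()},
            de_lncrnas={k: int(v) for k, v in d["de_lncrnas"].items()},
            planted_triplets=[
                Triplet(t["lncrna"], t["mrna"], frozenset(t["mirnas"]))
                for t in d["planted_triplets"]
            ],
            negative_correlated=[tuple(p) for p in d["negative_correlated"]],
            negative_shared=[
                Triplet(t["lncrna"], t["mrna"], frozenset(t["mirnas"]))
                for t in d["negative_shared"]
            ],
            planted_module_partition={
                k: int(v) for k, v in d["planted_module_partition"].items()
            },
        )


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _lnc_ids(n: int) -> list[str]:
    return [f"L{i:04d}" for i in range(1, n + 1)]


def _mirna_ids(n: int) -> list[str]:
    return [f"M{i:04d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw the TPM expression matrix and decide all planted structure.

    Log-scale model per feature and sample:
    baseline + group shift (DE features, case only) + noise.  For planted
    pairs the case-group noise splits into a shared latent factor and an
    independent remainder with variances rho*sd^2 and (1-rho)*sd^2, so the
    pair's population case correlation is rho while every feature keeps
    the same marginal variance.  Returned on the TPM scale via exp(v)-1.
    """
    config.validate()
    rng = config.rng("expression")

    genes = _gene_ids(config.n_genes)
    lncs = _lnc_ids(config.n_lncrnas)
    mirnas = _mirna_ids(config.n_mirnas)
    features = genes + lncs
    samples = [f"case{i:02d}" for i in range(1, config.n_case + 1)] + [
        f"ctrl{i:02d}" for i in range(1, config.n_control + 1)
    ]
    n_feat, n_samp = len(features), len(samples)
    case_cols = np.arange(config.n_case)

    # planted DE sets (floor rule) with random +/- direction
    n_deg = math.floor(config.n_genes * config.de_fraction_genes)
    n_del = math.floor(config.n_lncrnas * config.de_fraction_lncrnas)
    de_gene_idx = rng.choice(config.n_genes, size=n_deg, replace=False)
    de_lnc_idx = rng.choice(config.n_lncrnas, size=n_del, replace=False)
    de_genes = {
        genes[i]: int(d)
        for i, d in zip(sorted(de_gene_idx), rng.choice([-1, 1], size=n_deg))
    }
    de_lncrnas = {
        lncs[i]: int(d)
        for i, d in zip(sorted(de_lnc_idx), rng.choice([-1, 1], size=n_del))
    }

    # host lncRNA/mRNA pairs for planted triplets and negative controls,
    # all drawn (without replacement) from the DE features
    n_pairs = (
        config.n_planted_triplets
        + config.n_negative_correlated
        + config.n_negative_shared
    )
    pair_lncs = [
        sorted(de_lncrnas)[i]
        for i in rng.choice(len(de_lncrnas), size=n_pairs, replace=False)
    ]
    pair_genes = [
        sorted(de_genes)[i]
        for i in rng.choice(len(de_genes), size=n_pairs, replace=False)
    ]

    # per-community miRNA pools (disjoint), plus reserved miRNAs for the
    # negative controls, all outside the community pools
    pool_size = config.shared_mirnas_per_triplet + config.community_pool_extra
    shuffled = [mirnas[i] for i in rng.permutation(config.n_mirnas)]
    pools = [
        shuffled[c * pool_size:(c + 1) * pool_size] for c in range(config.n_communities)
    ]
    reserved = shuffled[config.n_communities * pool_size:]

    triplets: list[Triplet] = []
    partition: dict[str, int] = {}
    for i in range(config.n_planted_triplets):
        c = i % config.n_communities
        chosen = rng.choice(
            pool_size, size=config.shared_mirnas_per_triplet, replace=False
        )
        mset = frozenset(pools[c][j] for j in chosen)
        trip = Triplet(pair_lncs[i], pair_genes[i], mset)
        triplets.append(trip)
        partition[trip.lncrna] = c
        partition[trip.mrna] = c
        for mir in mset:
            partition[mir] = c

    off = config.n_planted_triplets
    negative_correlated = [
        (pair_lncs[off + i], pair_genes[off + i])
        for i in range(config.n_negative_correlated)
    ]
    off += config.n_negative_correlated
    negative_shared = []
    for i in range(config.n_negative_shared):
        base = i * config.shared_mirnas_per_triplet % max(
            1, len(reserved) - config.shared_mirnas_per_triplet
        )
        mset = frozenset(reserved[base:base + config.shared_mirnas_per_triplet])
        negative_shared.append(Triplet(pair_lncs[off + i], pair_genes[off + i], mset))

    truth = GroundTruth(
        de_genes=de_genes,
        de_lncrnas=de_lncrnas,
        planted_triplets=triplets,
        negative_correlated=negative_correlated,
        negative_shared=negative_shared,
        planted_module_partition=partition,
    )

    # log-scale values
    lo, hi = config.baseline_log_range
    baseline = rng.uniform(lo, hi, size=n_feat)
    log_vals = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n_feat, n_samp))

    feat_index = {f: i for i, f in enumerate(features)}
    for fid, direction in {**de_genes, **de_lncrnas}.items():
        log_vals[feat_index[fid], case_cols] += direction * config.de_log_fc

    # coexpressed pairs: replace case-group noise with factor + remainder
    rho = config.planted_correlation
    lam = config.noise_sd * math.sqrt(rho)
    resid_sd = config.noise_sd * math.sqrt(1.0 - rho)
    coexpressed = [(t.lncrna, t.mrna) for t in triplets] + list(negative_correlated)
    for lnc, gene in coexpressed:
        factor = rng.normal(0.0, 1.0, size=config.n_case)
        for fid in (lnc, gene):
            i = feat_index[fid]
            shift = 0.0
            if fid in de_genes:
                shift = de_genes[fid] * config.de_log_fc
            elif fid in de_lncrnas:
                shift = de_lncrnas[fid] * config.de_log_fc
            log_vals[i, case_cols] = (
                baseline[i]
                + shift
                + lam * factor
                + rng.normal(0.0, resid_sd, size=config.n_case)
            )

    tpm = np.clip(np.expm1(log_vals), 0.0, None)
    values = pd.DataFrame(tpm, index=features, columns=samples)
    kind = pd.Series(
        ["gene"] * config.n_genes + ["lncRNA"] * config.n_lncrnas,
        index=features, name="kind",
    )
    group = pd.Series(
        ["case"] * config.n_case + ["control"] * config.n_control,
        index=samples, name="group",
    )
    matrix = ExpressionMatrix(values=values, feature_kind=kind, group=group, is_log=False)
    return matrix, truth


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------

def simulate_interactions(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[InteractionTable, InteractionTable]:
    """Materialise (miRNA -> mRNA, miRNA -> lncRNA) edge tables.

    Planted triplets and shared-miRNA negative controls contribute their
    designated edges; every other (miRNA, target) pair receives a
    background edge with probability ``background_edge_prob``.  The
    members of correlated-no-shared-miRNA control pairs are excluded from
    background sampling and instead given small disjoint regulator sets,
    so their shared-miRNA count is exactly zero by construction.
    """
    config.validate()
    rng = config.rng("interactions")
    genes = _gene_ids(config.n_genes)
    lncs = _lnc_ids(config.n_lncrnas)
    mirnas = _mirna_ids(config.n_mirnas)

    mrna_edges: set[tuple[str, str]] = set()
    lnc_edges: set[tuple[str, str]] = set()
    for trip in truth.planted_triplets + truth.negative_shared:
        for mir in trip.mirnas:
            mrna_edges.add((mir, trip.mrna))
            lnc_edges.add((mir, trip.lncrna))

    # disjoint regulator sets for the correlated-but-no-shared controls
    pool_size = config.shared_mirnas_per_triplet + config.community_pool_extra
    used_in_pools = {
        m for m, c in truth.planted_module_partition.items() if m.startswith("M")
    }
    free = [m for m in mirnas if m not in used_in_pools]
    excluded = set()
    for i, (lnc, gene) in enumerate(truth.negative_correlated):
        a, b = free[(4 * i) % len(free)], free[(4 * i + 1) % len(free)]
        c, d = free[(4 * i + 2) % len(free)], free[(4 * i + 3) % len(free)]
        lnc_edges.add((a, lnc))
        lnc_edges.add((b, lnc))
        mrna_edges.add((c, gene))
        mrna_edges.add((d, gene))
        excluded.add(lnc)
        excluded.add(gene)

    p = config.background_edge_prob
    if p > 0:
        hits = rng.random((config.n_mirnas, config.n_genes)) < p
        for mi, gi in zip(*np.nonzero(hits)):
            if genes[gi] not in excluded:
                mrna_edges.add((mirnas[mi], genes[gi]))
        hits = rng.random((config.n_mirnas, config.n_lncrnas)) < p
        for mi, li in zip(*np.nonzero(hits)):
            if lncs[li] not in excluded:
                lnc_edges.add((mirnas[mi], lncs[li]))

    mrna_table = InteractionTable(
        edges=pd.DataFrame(sorted(mrna_edges), columns=["mirna", "target"]),
        target_kind="mRNA",
        source_tag="synthetic",
    )
    lnc_table = InteractionTable(
        edges=pd.DataFrame(sorted(lnc_edges), columns=["mirna", "target"]),
        target_kind="lncRNA",
        source_tag="synthetic",
    )
    return mrna_table, lnc_table


# ---------------------------------------------------------------------------
# drugs and annotations
# ---------------------------------------------------------------------------

def simulate_drug_targets(config: SimulationConfig, truth: GroundTruth) -> DrugTargetTable:
    """Drugs target random mRNAs, biased (50%) toward planted-triplet mRNAs."""
    config.validate()
    rng = config.rng("drugs")
    genes = _gene_ids(config.n_genes)
    triplet_mrnas = sorted({t.mrna for t in truth.planted_triplets})
    rows: set[tuple[str, str]] = set()
    for d in range(1, config.n_drugs + 1):
        drug = f"D{d:03d}"
        for _ in range(config.targets_per_drug):
            if triplet_mrnas and rng.random() < 0.5:
                target = triplet_mrnas[rng.integers(len(triplet_mrnas))]
            else:
                target = genes[rng.integers(config.n_genes)]
            rows.add((drug, target))
    return DrugTargetTable(
        edges=pd.DataFrame(sorted(rows), columns=["drug", "target"])
    )


def simulate_annotations(config: SimulationConfig, truth: GroundTruth) -> AnnotationSets:
    """One signal term holding all planted-triplet mRNAs plus random
    background terms of exactly ``genes_per_term`` genes each."""
    config.validate()
    rng = config.rng("annotations")
    genes = _gene_ids(config.n_genes)
    triplet_mrnas = sorted({t.mrna for t in truth.planted_triplets})

    signal = set(triplet_mrnas)
    others = [g for g in genes if g not in signal]
    while len(signal) < config.genes_per_term:
        signal.add(others[rng.integers(len(others))])

    sets = {"TERM_SIGNAL": frozenset(signal)}
    names = {"TERM_SIGNAL": "planted ceRNA target program"}
    for i in range(1, config.n_terms):
        term = f"T{i:03d}"
        idx = rng.choice(config.n_genes, size=config.genes_per_term, replace=False)
        sets[term] = frozenset(genes[j] for j in idx)
        names[term] = f"background term {i}"
    return AnnotationSets(sets=sets, names=names, universe=frozenset(genes))


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    expression: ExpressionMatrix
    mirna_mrna: InteractionTable
    mirna_lncrna: InteractionTable
    drugs: DrugTargetTable
    annotations: AnnotationSets
    truth: GroundTruth
    config: SimulationConfig = field(repr=False, default=None)


def simulate_all(config: SimulationConfig) -> SimulatedStudy:
    """Run every generator off one seed and bundle the results."""
    expr, truth = simulate_expression(config)
    mrna_tab, lnc_tab = simulate_interactions(config, truth)
    drugs = simulate_drug_targets(config, truth)
    annotations = simulate_annotations(config, truth)
    return SimulatedStudy(
        expression=expr,
        mirna_mrna=mrna_tab,
        mirna_lncrna=lnc_tab,
        drugs=drugs,
        annotations=annotations,
        truth=truth,
        config=config,
    )


def write_fixtures(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every fixture file in the io-module formats plus truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "mirna_mrna": outdir / "mirna_mrna.tsv",
        "mirna_lncrna": outdir / "mirna_lncrna.tsv",
        "drugs": outdir / "drug_targets.tsv",
        "annotations": outdir / "terms.gmt",
        "truth": outdir / "truth.json",
        "config": outdir / "sim_config.json",
    }
    write_expression_matrix(study.expression, paths["expression"], paths["metadata"])
    write_interaction_table(study.mirna_mrna, paths["mirna_mrna"])
    write_interaction_table(study.mirna_lncrna, paths["mirna_lncrna"])
    write_drug_target_table(study.drugs, paths["drugs"])
    write_annotation_gmt(study.annotations, paths["annotations"])
    study.truth.to_json(paths["truth"])
    if study.config is not None:
        Path(paths["config"]).write_text(
            json.dumps(asdict(study.config), indent=1, sort_keys=True)
        )
    return paths
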