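"""Readers and writers for every external format the pipeline touches.

Formats
-------
* expression TSV (features x samples) with a metadata sidecar TSV giving
  each feature's kind (``gene`` / ``lncRNA``) and each sample's group
  (``case`` / ``control``),
* two-column miRNA-target interaction TSVs,
* drug-target TSVs,
* GMT term collections,
* GraphML / SIF / plain edge TSV for typed networks.

All TSVs are tab-separated UTF-8; lines starting with ``#`` are ignored.
Writers and readers round-trip: re-reading a written file reproduces an
equal container.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("gene", "lncRNA")
SAMPLE_GROUPS = ("case", "control")
NODE_TYPES = ("lncRNA", "miRNA", "mRNA", "drug")
EDGE_TYPES = ("mirna_lncrna", "mirna_mrna", "drug_target")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Features x samples expression with group and feature-kind metadata.

    ``values`` holds non-negative TPM when ``is_log`` is False, or
    log(TPM + 1) otherwise.  ``feature_kind`` and ``group`` are Series
    indexed by feature / sample id.
    """

    values: pd.DataFrame
    feature_kind: pd.Series
    group: pd.Series
    is_log: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx, cols = self.values.index, self.values.columns
        for name, labels in (("feature", idx), ("sample", cols)):
            dup = labels[labels.duplicated()]
            if len(dup):
                raise ValueError(f"duplicate {name} id: {dup[0]!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if not self.is_log and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative TPM value at feature {idx[i]!r}, sample {cols[j]!r}"
            )
        if not self.feature_kind.index.equals(idx):
            raise ValueError("feature_kind index does not match matrix features")
        if not self.group.index.equals(cols):
            raise ValueError("group index does not match matrix samples")
        bad_kind = set(self.feature_kind) - set(FEATURE_KINDS)
        if bad_kind:
            raise ValueError(f"unknown feature kind(s): {sorted(bad_kind)}")
        bad_grp = set(self.group) - set(SAMPLE_GROUPS)
        if bad_grp:
            raise ValueError(f"unknown sample group(s): {sorted(bad_grp)}")

    # -- convenience views ---------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.group.index[self.group == group])

    def features_of_kind(self, kind: str) -> list[str]:
        return list(self.feature_kind.index[self.feature_kind == kind])

    def require_group_sizes(self, minimum: int = 2) -> None:
        for g in SAMPLE_GROUPS:
            n = int((self.group == g).sum())
            if n < minimum:
                raise ValueError(
                    f"group {g!r} has {n} samples; at least {minimum} required"
                )

    # -- transforms ----------------------------------------------------------

    def to_log(self, base: float = math.e) -> "ExpressionMatrix":
        """Return a log(x+1) copy (identity if already log scale)."""
        if self.is_log:
            return self
        vals = np.log1p(self.values.to_numpy(dtype=float))
        if base != math.e:
            vals = vals / math.log(base)
        return replace(
            self,
            values=pd.DataFrame(
                vals, index=self.values.index, columns=self.values.columns
            ),
            is_log=True,
        )

    def to_tpm(self, base: float = math.e) -> "ExpressionMatrix":
        """Return a linear-TPM copy, inverting log(x+1)."""
        if not self.is_log:
            return self
        vals = self.values.to_numpy(dtype=float)
        if base != math.e:
            vals = vals * math.log(base)
        vals = np.clip(np.expm1(vals), 0.0, None)
        return replace(
            self,
            values=pd.DataFrame(
                vals, index=self.values.index, columns=self.values.columns
            ),
            is_log=False,
        )

    def equals(self, other: "ExpressionMatrix", atol: float = 1e-9) -> bool:
        return (
            self.is_log == other.is_log
            and self.values.index.equals(other.values.index)
            and self.values.columns.equals(other.values.columns)
            and self.feature_kind.equals(other.feature_kind)
            and self.group.equals(other.group)
            and np.allclose(self.values.to_numpy(), other.values.to_numpy(), atol=atol)
        )


@dataclass
class InteractionTable:
    """Deduplicated miRNA -> target edge list of one target kind."""

    edges: pd.DataFrame  # columns: mirna, target
    target_kind: str  # "mRNA" or "lncRNA"
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.target_kind not in ("mRNA", "lncRNA"):
            raise ValueError(f"unknown target kind {self.target_kind!r}")
        self.edges = (
            self.edges[["mirna", "target"]]
            .astype(str)
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def mirnas(self) -> set[str]:
        return set(self.edges["mirna"])

    @property
    def targets(self) -> set[str]:
        return set(self.edges["target"])

    def mirnas_by_target(self) -> dict[str, frozenset[str]]:
        grouped = self.edges.groupby("target")["mirna"].agg(frozenset)
        return dict(grouped)


@dataclass
class DrugTargetTable:
    """Deduplicated drug -> target-gene edge list."""

    edges: pd.DataFrame  # columns: drug, target

    def __post_init__(self) -> None:
        self.edges = (
            self.edges[["drug", "target"]]
            .astype(str)
            .drop_duplicates()
            .reset_index(drop=True)
        )
        if ((self.edges["drug"] == "") | (self.edges["target"] == "")).any():
            raise ValueError("empty drug or target id in drug-target table")

    def __len__(self) -> int:
        return len(self.edges)

    def targets_by_drug(self) -> dict[str, frozenset[str]]:
        return dict(self.edges.groupby("drug")["target"].agg(frozenset))


@dataclass
class AnnotationSets:
    """Term -> gene-set mapping (the in-memory form of a GMT file)."""

    sets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise ValueError(f"annotation term {term!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.sets)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path: str | Path,
    meta_path: str | Path,
    apply_log: bool = False,
) -> ExpressionMatrix:
    """Load a features x samples TSV plus its metadata sidecar.

    The sidecar has columns ``id``, ``role`` (``feature`` | ``sample``) and
    ``label`` — the feature kind for feature rows, the sample group for
    sample rows.  With ``apply_log`` every value v is replaced by
    log(v + 1) (natural log) and ``is_log`` is set.
    """
    raw = _read_tsv(path, index_col=0)
    values = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str))
    arr = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"non-numeric cell at feature {raw.index[i]!r}, sample {col!r}: "
                f"{raw[col].iloc[i]!r}"
            )
        arr[:, j] = converted.to_numpy(dtype=float)
    values.iloc[:, :] = arr
    values = values.astype(float)

    meta = _read_tsv(meta_path)
    required = {"id", "role", "label"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata sidecar must have columns {sorted(required)}")
    feats = meta[meta["role"] == "feature"].set_index("id")["label"]
    samps = meta[meta["role"] == "sample"].set_index("id")["label"]
    missing_f = set(values.index) - set(feats.index)
    if missing_f:
        raise ValueError(f"feature(s) missing from metadata: {sorted(missing_f)[:5]}")
    missing_s = set(values.columns) - set(samps.index)
    if missing_s:
        raise ValueError(f"sample(s) missing from metadata: {sorted(missing_s)[:5]}")
    kind = feats.reindex(values.index)
    kind.name = "kind"
    group = samps.reindex(values.columns)
    group.name = "group"

    mat = ExpressionMatrix(values=values, feature_kind=kind, group=group, is_log=False)
    if apply_log:
        mat = mat.to_log()
    logger.info(
        "read expression matrix %s: %d features x %d samples",
        path, values.shape[0], values.shape[1],
    )
    return mat


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, meta_path: str | Path
) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")
    meta = pd.concat(
        [
            pd.DataFrame(
                {
                    "id": matrix.values.index,
                    "role": "feature",
                    "label": matrix.feature_kind.to_numpy(),
                }
            ),
            pd.DataFrame(
                {
                    "id": matrix.values.columns,
                    "role": "sample",
                    "label": matrix.group.to_numpy(),
                }
            ),
        ]
    )
    meta.to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interaction / drug tables
# ---------------------------------------------------------------------------

def read_interaction_table(
    path: str | Path, target_kind: str, source_tag: str = ""
) -> InteractionTable:
    """Read a two-column (miRNA, target) TSV; duplicates are dropped.

    A header line is recognised when the first row contains the tokens
    ``mirna`` and ``target`` (case-insensitive).
    """
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            if lineno == 1 and parts[0].lower() in ("mirna", "regulator"):
                continue
            rows.append((parts[0], parts[1]))
    if not rows:
        raise ValueError(f"{path}: no interaction rows found")
    edges = pd.DataFrame(rows, columns=["mirna", "target"])
    n_raw = len(edges)
    table = InteractionTable(edges=edges, target_kind=target_kind, source_tag=source_tag)
    logger.info(
        "read %s: %d rows, %d unique %s edges", path, n_raw, len(table), target_kind
    )
    return table


def write_interaction_table(table: InteractionTable, path: str | Path) -> None:
    table.edges.to_csv(path, sep="\t", index=False)


def read_drug_target_table(path: str | Path) -> DrugTargetTable:
    df = _read_tsv(path)
    if not {"drug", "target"}.issubset(df.columns):
        df = _read_tsv(path, header=None, names=["drug", "target"])
    return DrugTargetTable(edges=df[["drug", "target"]])


def write_drug_target_table(table: DrugTargetTable, path: str | Path) -> None:
    table.edges.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_annotation_gmt(path: str | Path) -> AnnotationSets:
    """Read standard GMT: term <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno}")
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if term in sets:
                raise ValueError(f"{path}: duplicate term {term!r} at line {lineno}")
            sets[term] = frozenset(genes)
            names[term] = desc
    return AnnotationSets(sets=sets, names=names)


def write_annotation_gmt(annotations: AnnotationSets, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in annotations.sets:
            desc = annotations.names.get(term, term)
            genes = "\t".join(sorted(annotations.sets[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


# ---------------------------------------------------------------------------
# typed networks
# ---------------------------------------------------------------------------

def write_network(network: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a typed network as GraphML, SIF or a plain edge TSV.

    GraphML carries ``node_type`` and ``edge_type`` attributes; SIF uses
    ``edge_type`` as the relation token.
    """
    path = Path(path)
    if format == "graphml":
        # rebuild in sorted order so output bytes are deterministic
        g = nx.Graph()
        for node in sorted(network.nodes):
            g.add_node(node, **network.nodes[node])
        for u, v in sorted(tuple(sorted(e)) for e in network.edges):
            g.add_edge(u, v, **network.edges[u, v])
        nx.write_graphml(g, path)
    elif format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in network.edges):
                rel = network.edges[u, v].get("edge_type", "interacts")
                fh.write(f"{u}\t{rel}\t{v}\n")
    elif format == "edge_tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tedge_type\tsource_type\ttarget_type\n")
            for u, v in sorted(tuple(sorted(e)) for e in network.edges):
                fh.write(
                    f"{u}\t{v}\t{network.edges[u, v].get('edge_type', '')}\t"
                    f"{network.nodes[u].get('node_type', '')}\t"
                    f"{network.nodes[v].get('node_type', '')}\n"
                )
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path) -> nx.Graph:
    """Read a GraphML network written by :func:`write_network`."""
    return nx.read_graphml(path, node_type=str)
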