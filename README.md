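# cerna-scope

Competing-endogenous-RNA (ceRNA) network inference for small case/control
expression studies.

lncRNAs can act as miRNA "sponges": by sequestering a shared miRNA they
de-repress that miRNA's mRNA targets, coupling the lncRNA's and the mRNA's
abundance.  `cerna-scope` screens a TPM expression matrix (e.g. blood-exosome
RNA-seq with a handful of disease samples against a larger control group)
together with miRNA-target interaction tables for such lncRNA–mRNA ceRNA
pairs, assembles them into a typed lncRNA–miRNA–mRNA network with a
drug-target overlay, cuts the network into modules and annotates the module
genes by set enrichment.  It is written for bioinformaticians who want a
tested, scriptable version of this common ceRNA workflow — plus a synthetic
study generator with planted ground truth, so every stage can be validated
without access to any cohort data.

## Method

1. **Differential expression.**  Each feature is tested with a Welch
   (unequal-variance) *t*-test on log(x+1) values; the fold change
   FC = mean_case / mean_control is computed on the linear TPM scale.
   Genes and lncRNAs are corrected as separate Benjamini–Hochberg
   families; a feature is significant at FDR < 0.05 (an optional FC
   cutoff is off by default).
2. **Shared-miRNA test.**  For every (DE lncRNA, DE gene) pair sharing at
   least one miRNA regulator, with *m* miRNAs in the universe, *t* of
   them targeting the mRNA, *n* targeting the lncRNA and *r* shared, the
   p-value is the hypergeometric upper tail

   P = 1 − Σᵢ₌₀^{r−1} C(t, i) · C(m−t, n−i) / C(m, n),

   BH-adjusted over all enumerated pairs (one family).
3. **Coexpression filter.**  Pearson correlation of the pair is computed
   per group on log-scale values.  Three explicit modes resolve what
   "coexpressed" means: `both_groups` (r > 0.5 and p < 0.05 in both
   groups), `case_only` (case group alone — appropriate for coexpression
   gained in disease), and `delta` (r_case − r_control > 0.5 with case
   p < 0.05).  A pair is **accepted** when its shared-miRNA FDR < 0.05
   and the coexpression criterion passes.
4. **Network & drugs.**  Accepted pairs contribute miRNA–lncRNA and
   miRNA–mRNA edges to an undirected typed graph; drugs from a
   drug-target table attach to the mRNA nodes they target.
5. **Modules.**  Girvan–Newman edge-betweenness clustering with
   modularity-based cut selection; components with fewer than 3 nodes
   are hidden.
6. **Enrichment.**  Hypergeometric over-representation of network /
   module genes in GMT term sets (same tail kernel as step 2), BH
   corrected.

## Worked example

A full synthetic run (all defaults: 2000 genes, 300 lncRNAs, 150 miRNAs,
6 case vs 32 control samples, 20 planted ceRNA triplets):

```sh
cerna-scope run --seed 1 --out demo_run
```

prints the manifest's stage counts:

```json
{
 "accepted_pairs": 21,
 "candidate_pairs": 260,
 "deg_percent": 15,
 "degs": 303,
 "del_percent": 12,
 "dels": 37,
 "edges": {"drug_target": 73, "mirna_lncrna": 76, "mirna_mrna": 76, "total": 225},
 "features_gene": 2000,
 "features_lncrna": 300,
 "modularity": 0.7479224376731302,
 "module_sizes": [30, 37, 28, 27],
 "modules": 4,
 "nodes": {"drug": 30, "lncRNA": 19, "mRNA": 19, "miRNA": 24, "total": 92}
}
```

Reading: 303 of 2000 genes (15%) and 37 of 300 lncRNAs (12%) come out
differentially expressed; 260 DE pairs share at least one miRNA, and 21
survive the shared-miRNA FDR and the case-group coexpression filter —
19 of the 20 planted triplets plus two background pairs
(`manifest.json` reports recall 0.95 / precision 0.90 against the
planted truth).  The network collects those pairs' 76 + 76 regulator
edges, 30 drugs attach to the 19 mRNAs, and betweenness clustering
recovers 4 modules — matching the 4 planted miRNA communities — at
modularity Q = 0.75.  Per-stage tables (`differential_expression.tsv`,
`cerna_candidates.tsv`, `network.graphml`, `modules/`,
`enrichment_*.tsv`) land in `demo_run/`.

Each stage is also a subcommand (`simulate`, `de`, `cerna`, `network`,
`modules`, `enrich`) operating on plain TSV/GMT/GraphML files, and a
library API (`import cerna_scope`) exposes every operation directly.

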