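# Methods

## Statistical model

### Differential expression

Expression is assumed TPM-normalised and is analysed after a log(x+1)
transform (natural log; the base is configurable and only rescales the
statistic's inputs, not the test).  The per-feature test is Welch's
unequal-variance *t* with Satterthwaite degrees of freedom.  Welch
rather than Student is deliberate: the intended designs are heavily
unbalanced (6 vs 32 by default), where a pooled variance estimate is
dominated by the larger group and the test size is not maintained under
heteroscedasticity.  Fold change is computed on the linear TPM scale as
mean_case / mean_control (optional pseudocount, default 0; a 0/0 ratio
is reported missing and never significant).

Genes and lncRNAs form separate Benjamini–Hochberg families because the
two feature classes are screened and reported separately; mixing them
would let the (larger, typically better-powered) gene family drive the
lncRNA thresholds.  Significance is FDR < 0.05 alone.  A fold-change
cutoff exists (`fc_cutoff`) but defaults to off: fold change is
descriptive output, not a second filter, unless the user opts in.

Degenerate inputs follow fixed conventions: zero variance in both groups
gives p = 1 for equal means and p = 0 otherwise (logged).

### Shared-miRNA test

For a lncRNA with *n* miRNA regulators and an mRNA with *t*, out of *m*
miRNAs total, the probability of observing ≥ *r* shared regulators by
chance is the hypergeometric upper tail.  The tail is summed directly
(from *r* upward) with log-gamma binomials, which keeps small p-values
accurate where `1 − lower_tail` would cancel; *r* = 0 returns 1 by
convention.  The same kernel serves the gene-set enrichment module — a
single implementation, two call sites.

The universe *m* defaults to the number of distinct miRNAs appearing in
the union of the two loaded interaction tables: it is the only universe
observable from the data, and it makes the test self-consistent with the
regulator sets actually used.  A fixed external constant (e.g. a global
human miRNA count) can be supplied instead; a larger *m* makes every
overlap look more surprising, so the choice is conservative by default.
Pairs with *r* = 0 are excluded before BH adjustment — they carry p = 1
by construction and would only dilute the family.  All enumerated pairs
form one BH family.

### Coexpression filter

Pearson correlation between the pair's log-scale profiles is computed
within each group; the p-value is the usual two-sided *t* on k−2 df.
With 6 case samples that is 4 df, so p < 0.05 demands sample r > 0.81 —
a warning is emitted whenever a group has fewer than 8 samples.  Three
acceptance modes are exposed because "coexpressed in disease and normal"
and "case-minus-control difference > 0.5" are different criteria and
both are defensible:

* `both_groups` — r > 0.5 ∧ p < 0.05 in case and in control; the
  library-level default (coexpression as a stable property of the pair);
* `case_only` — the case conditions alone; the pipeline default,
  because the planted synthetic design (and the disease-gained-sponging
  hypothesis generally) predicts correlation that exists only in the
  disease group, which the control group cannot corroborate;
* `delta` — r_case − r_control > 0.5 ∧ p_case < 0.05, the explicitly
  differential form.

Positive correlation is required (signed, not absolute): ceRNA
co-regulation predicts positive lncRNA–mRNA coupling.  Constant
profiles yield NaN correlations, which fail every mode without aborting
the batch.

### Network, modules, drugs

The network is undirected with exactly three edge types —
miRNA–lncRNA, miRNA–mRNA, drug–mRNA.  The lncRNA–mRNA pairing itself is
not materialised as an edge: it lives in the candidate table, and the
graph records the regulator relations it was inferred from.  Type
invariants (allowed endpoint pairs, no self-loops) are asserted on every
build.

Module extraction is Girvan–Newman: repeatedly delete the
highest-edge-betweenness edge (unweighted shortest paths; ties broken by
lexicographic edge order so runs are deterministic), track the component
partitions, and return the partition maximising Newman modularity Q on
the original graph.  The trivial unsplit partition competes on equal
terms, so cliques come back whole.  Components below `min_size`
(default 3) are hidden from the module list.  This is the canonical
algorithm matching a "betweenness centrality clustering" description;
it is an emulation of that class of method, not a bit-exact reproduction
of any particular service.  Modules are cut on the RNA-only subgraph;
drugs are overlaid afterwards, per module, so drug degree cannot distort
the community structure.

Drugs attach only to mRNA nodes (drug targets are proteins/genes).  A
drug targeting no network gene is not added.

### Enrichment

Over-representation only (upper tail), BH across all tested terms,
terms with zero query overlap skipped.  The universe defaults to the
annotation collection's gene universe (all genes in the GMT if no
explicit universe is given) and can be switched to the expression
matrix's gene set; the background choice is logged because it is the
single most result-changing knob in ORA.

## Synthetic study generator

The generator emulates the *shape* of a small unbalanced exosome
RNA-seq cohort, not any real dataset's empirical distribution:
non-negative TPM values analysed after log(x+1), log-scale baselines
uniform on [1, 6] (≈ 3–400 TPM), i.i.d. Gaussian log-scale noise
(sd 0.5), 6 case vs 32 control samples, 15% of genes and 12% of lncRNAs
differentially expressed (floor rule, ±de_log_fc on the log scale in
the case group, default 1.5 ≈ 4.5-fold — a clearly-dysregulated-signal
regime).

Planted ceRNA triplets are drawn from the DE features.  Each triplet's
lncRNA and mRNA share, in case samples only, a latent factor that
replaces part of their noise: loading λ = sd·√ρ and residual sd·√(1−ρ),
so the pair's population case correlation is ρ while every feature keeps
the same marginal variance (DE detection is unaffected).  The default
ρ = 0.97 comes from a power calculation, fixed before any tuning: the
case-group correlation test at 6 samples rejects only for sample
r > 0.81, and Fisher-z power at ρ = 0.97 is ≈ 0.95 per pair, putting the
expected recall of 20 triplets ≈ 3 binomial standard deviations above
0.8.  A visibly weaker choice (ρ ≈ 0.8) has ≈ 50% per-pair power at this
sample size and would make recovery a coin flip — that is a property of
6-sample correlation testing, not of the method.

Triplets are assigned round-robin to `n_communities` (default 4) blocks
whose shared miRNAs come from disjoint per-community pools (pool size
6, triplet draws 4), so triplets within a block overlap in regulators
and the resulting network has a planted community partition.

Negative controls: pairs with the same latent-factor coexpression but
zero shared miRNAs (their members get disjoint dedicated regulators and
are excluded from background edge sampling, so r = 0 holds exactly),
and pairs with a planted shared-miRNA set but no latent factor.
Background interaction edges are Bernoulli(0.005) per (miRNA, target) —
sparse, as curated interaction databases are relative to the full
bipartite grid.  Drugs pick 5 targets each, half biased toward planted
mRNAs; annotations contain one signal term holding all planted-triplet
mRNAs plus background terms of exactly `genes_per_term` random genes.

All randomness flows from one integer seed; each generator stage uses
an independent fixed-offset substream, so partial re-runs reproduce.

What passing on these fixtures shows — and does not.  Recovery of
planted triplets demonstrates that the filters compose correctly and
have the designed power under Gaussian log-scale noise with exact
group labels.  Real exosome data add overdispersion, batch structure,
correlated features beyond the planted pairs, and annotation errors in
the interaction tables; none of these are modelled, so synthetic
recall/precision are upper bounds, not forecasts.

## Problem sizes and determinism

Default generator sizes (2000 genes, 300 lncRNAs, 150 miRNAs) keep a
full pipeline run at a few seconds while leaving every stage
non-trivial (≈ 300 DEGs × 37 DELs pair enumeration, ≈ 90-node network);
they are deliberate scale-downs of a transcriptome-wide screen, chosen
as the package's standard validation conditions.  The exhaustive
hypergeometric check enumerates all regulator subsets for every
(m ≤ 12, t, n, r); brute-force betweenness enumerates all shortest
paths on graphs of ≤ 8 nodes.  Girvan–Newman is O(E²·V) and intended
for the resulting module-scale networks (hundreds of edges), not for
graphs with tens of thousands of edges.

Manifests contain no timestamps, so identical config + seed gives
byte-identical manifests; GraphML is written in sorted node/edge order
for the same reason.

## Known limitations

* The shared-miRNA test treats interaction tables as binary truth; no
  interaction confidence weighting.
* Correlation-based filtering at n = 6 has low power by construction;
  the `case_only`/`delta` modes exist precisely because the both-group
  criterion is rarely attainable for disease-gained coexpression.
* No conditional-mutual-information or partial-correlation ceRNA
  scores; the inference is exactly the two-filter composition above.
* Module "significance" is a size filter only; no permutation test on
  module quality is performed.
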