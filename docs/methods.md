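# Methods

## Differential expression model

Counts for feature *f* in sample *s* are modeled as negative binomial with
mean μ_fs = q_f · sf_s and dispersion α_f, where sf_s is a sample size
factor and variance follows var = μ + αμ². The stage proceeds as:

- **Normalization.** Median-of-ratios size factors: for features with
  positive counts in every sample, sf_s = median_f(count_fs / geomean_f).
  When no feature is positive everywhere the estimator refuses, and a
  `pseudo_reference=True` flag switches the geometric mean to positive
  entries only (a poscounts-style fallback for sparse matrices).
- **Dispersion.** Per-feature method of moments, pooled across the two
  groups with degree-of-freedom weights and floored at zero:
  α = max(0, (s² − m)/m²). No shrinkage toward a mean–dispersion trend is
  applied.
- **Effect and test.** log2FC = log2((mean_T + ε)/(mean_N + ε)) with
  pseudo-count ε = 0.5 and tumor as the numerator (the sign convention is
  fixed: positive means higher in tumors). The delta-method standard error
  propagates the NB variance of each group mean — the Poisson part picks up
  the mean reciprocal size factor of the group — and z = log2FC/SE is
  referred to a standard normal, two-sided. Features with zero counts in
  every sample are not tested and are excluded from the BH denominator,
  mirroring the effect of independent filtering.
- **Multiple testing.** Benjamini–Hochberg step-up (via statsmodels), with
  monotonicity enforced.
- **Calls.** Genes: adjusted p ≤ α and |log2FC| ≥ 1 (inclusive); miRNAs:
  adjusted p ≤ α and |log2FC| > 0 (strict). α defaults to 0.05.

This is deliberately simpler than a full DESeq2 fit (no dispersion
shrinkage, no outlier replacement, no LFC shrinkage). The simplification is
testable: under the null the rejection rate at p ≤ 0.05 measures 0.05–0.06
(the normal reference instead of a t-like one costs a little
anticonservatism; the zero floor on α compensates for part of it), and with
10% planted effects the observed FDR at BH 0.05 stays below 0.10 — both
checked in the suite.

The "VST" used for patient stratification is log2(normalized + 1). Its only
downstream consumers (quartile grouping, rank tests, Pearson trends) depend
on ranks or near-linear structure, so a monotone surrogate suffices.

## Overlap groups and circuit assembly

Gene symbols are uppercased and miRNA IDs lowercased before matching;
mature-vs-precursor naming is resolved only through an explicit user alias
table, never guessed. A protein table with conflicting duplicate directions
is rejected at load time. Interaction rows whose support type contains
"negative" (case-insensitive substring) are removed and surviving
(miRNA, gene) pairs deduplicated across source databases.

The four overlap groups are plain intersections of directional DEG sets with
directional protein sets. Circuits are then the validated edges whose
endpoints satisfy one of three direction triples:

| circuit | miRNA | mRNA | protein | mechanism |
|---------|-------|------|---------|-----------|
| RRC1 | up | down | down | target degradation |
| RRC2 | up | up | down | translational repression |
| IRC | down | up | up | lost repression |

The down-mRNA/up-protein group is intentionally not made into a circuit: a
miRNA cannot lower an mRNA while raising its protein, so such pairs would
confound the mechanism-based interpretation. Assembly is a pure set
operation — idempotent, order-independent, and incapable of inventing edges —
and empty circuits are valid outputs.

## Hub scoring

MCC(v) = Σ_{maximal cliques C ∋ v} (|C|−1)!, computed from Bron–Kerbosch
clique enumeration (networkx). Isolated nodes score 0; this convention
(rather than a +1 singleton term) keeps the identity MCC = degree exact on
bipartite graphs, and isolated nodes cannot occur in assembled circuits
anyway. Target hubs are the top k (default 5) by MCC with a lexicographic
tie-break on ID for reproducibility. Regulator hubs are ranked by out-degree
and the top k is expanded to include every regulator tied with the k-th
value — this tie rule is why published regulator-hub tables often contain
more than five rows. Coverage is 100 × out-degree / (distinct targets in the
given circuit graph), rounded to one decimal; the denominator is always
taken from the graph itself rather than from any externally stated target
count.

## Enrichment

ORA uses the hypergeometric upper tail P(X ≥ k) for an overlap of k between
a query of size n and a set of size K in a background of size N. The default
background is the set of features tested for DE — standard ORA practice —
and is overridable. BH adjustment is applied within each category
independently, so pathway collections and miRNA-function collections do not
share a correction family. Query or set members outside the background are
dropped (logged), and a query fully disjoint from the background raises an
error naming the ID-space mismatch.

## Clinical statistics

- **ROC/AUC** via the rank statistic with half credit for ties (equivalent
  to U/(n₊n₋)); orientation is flipped to keep AUC ≥ 0.5 and the flip is
  recorded, so both up- and down-regulated markers report discriminative
  power. Bands: ≥0.9 excellent, ≥0.8 good, ≥0.7 fair, ≥0.6 poor, else
  failure.
- **Quartile stratification** takes the floor(n/4) lowest and highest
  samples with a lexicographic sample-ID tie-break at the boundary; a
  180-patient cohort gives 45 per group. The floor convention is stated
  explicitly because exact division hides it.
- **Kaplan–Meier / log-rank** wrap lifelines; the statistic is
  (ΣO−E)²/ΣVar with p from a 1-df chi-square (the universal convention; a
  permutation reference exists only in the tests). Two all-censored groups
  yield a flagged, undefined result rather than a number.
- **Kruskal–Wallis / Mann–Whitney** wrap scipy with tie correction;
  Mann–Whitney uses exact enumeration when n_a+n_b ≤ 12 with no ties. The
  all-tied degenerate Kruskal–Wallis input is defined as H = 0. T-stage
  pairwise p-values are reported unadjusted by default (mirroring the usual
  pairwise-bar presentation), with an opt-in BH flag.
- **Pearson correlation** uses the t transform with n−2 df; a pair is
  inverse-significant iff p ≤ 0.05 and r ≤ −0.3. The r gate matters: a huge
  cohort can make r = −0.1 highly significant, but it is not a biologically
  meaningful inverse relationship.

## Synthetic-data generator

The generator emulates the study conditions the pipeline is designed for:

- **Cohort**: 180 tumor / 18 normal samples by default (the strong imbalance
  of the emulated cohort is part of the conditions, not a nuisance).
- **Counts**: NB with one shared dispersion α (default 0.15, a typical bulk
  RNA-seq value), base means log-uniform in [10, 1000], and sample size
  factors log-uniform in [0.5, 2] so normalization is nontrivial. Default
  feature counts are desk-scale (4000 genes, 800 miRNAs) with DE fractions
  of 0.25 / 0.23, matching the proportion of features the emulated cohort
  calls differential; planted |log2FC| defaults to 2.
- **Interactions**: planted true edges among DE features ("validated"
  support), decoys confined to non-DE features so no decoy can reach a
  circuit, plus round(frac_negative · edges) rows labelled "negative" that
  the filter must remove. Databases cycle through three named sources.
- **Proteins**: every planted DE gene appears once; exactly
  round(frac · n) genes are direction-concordant with their mRNA (default
  0.85), the rest flipped — the flipped ones populate the discordant overlap
  groups.
- **Clinical**: T stage is drawn from the base distribution (6/29/40/25%)
  shifted on the cumulative-logit scale by the designated gene's expression
  quantile; the shift (default 4.0 across the quantile range) is sized so
  the planted ordinal signal is detectable by Kruskal–Wallis at the default
  cohort size. Survival is exponential with log-hazard = log(0.01/month) +
  0.5 per SD of the hazard gene's log2 expression, censored by a 120-month
  administrative horizon plus exponential dropout (rate 1/240 per month),
  which yields realistic censoring fractions near 50%.

All randomness derives from a single seed through named SeedSequence
streams, so fixed-seed outputs are bit-identical across runs and each
component can be regenerated independently.

What the generator does **not** emulate: batch structure, library-type
differences, correlated expression between a miRNA and its targets within
the tumor group (counts are independent given the group), realistic gene
symbol vocabularies, or proteome intensities (only directions are needed
downstream). Passing tests therefore demonstrate the pipeline's statistical
correctness and recovery behavior under the assumed model, not robustness
to the artifacts of real cohorts; in particular, regulator–target Pearson
correlations on synthetic tumors are null by construction.

## Problem sizes and numerical choices

The suite and the acceptance script run at desk scale, chosen to make each
targeted check statistically meaningful while keeping the full run in the
minutes range: DE calibration uses 2000 features at 20 vs 20 (one null run
for type-I error; 20 seeds pooled for FDR), pipeline recovery uses 600
genes / 150 miRNAs at 30 vs 30 with |log2FC| = 3 and low dispersion, and
the end-to-end study uses the generator defaults. Deterministic tie-breaks
(lexicographic IDs) are used wherever a ranking could be ambiguous;
coverage percentages are rounded to one decimal; ε = 0.5 keeps fold changes
finite for one-sided dominance features, which are correctly called.

## Known limitations

- The DE stage is a simplified NB Wald test; it will not numerically match
  a full DESeq2 analysis, and its FDR control relies on a 10% margin over
  the nominal BH level to absorb dispersion misestimation.
- ID harmonization is purely case-based plus the optional alias table; no
  symbol-vintage resolution is attempted.
- The log-rank p uses the chi-square approximation, which is coarse for
  very small groups (the tests quantify the error against permutation on
  n = 10).
- Enrichment reproduces the ORA statistic, not any specific tool's curated
  collections, combined scores, or backgrounds.
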