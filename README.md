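# regcircuit

Integrative miRNA–mRNA–protein regulatory-circuit analysis for tumor/normal
cohorts, with a synthetic-data generator for end-to-end validation.

## The problem

In many cancers — intestinal-subtype gastric adenocarcinoma is the motivating
case — gene regulation can only be understood by combining three layers:
microRNA expression, mRNA expression, and protein abundance. A miRNA that is
up in tumors may degrade its target (mRNA and protein both down), or repress
translation only (mRNA up, protein down); a miRNA that is down may simply fail
to repress (mRNA and protein both up). `regcircuit` implements this analysis
as a reusable, tested pipeline for anyone with tumor/normal count matrices, a
protein differential-expression table, and a validated miRNA→gene interaction
table:

1. **Differential expression** — median-of-ratios normalization and a
   negative-binomial Wald test (a documented simplification of the DESeq2
   model). Genes are called at adjusted *p* ≤ 0.05 and |log2FC| ≥ 1, miRNAs at
   adjusted *p* ≤ 0.05 and |log2FC| > 0.
2. **Directional overlap** — DEGs are intersected with the protein table into
   four groups by (mRNA, protein) direction: down/down, up/up, up/down, down/up.
3. **Circuit assembly** — validated interactions (rows whose support type
   mentions "negative" are excluded) connect DEMs to the groups under the
   canonical miRNA mechanism, yielding three circuits: **RRC1** (up-miRNA →
   down/down: degradation), **RRC2** (up-miRNA → up/down: translational
   repression), **IRC** (down-miRNA → up/up: lost repression). The down/up
   group contradicts the mechanism and produces no circuit.
4. **Hubs** — target genes are ranked by maximal clique centrality,
   MCC(v) = Σ over maximal cliques *C* ∋ v of (|C|−1)!, which on a bipartite
   circuit equals the number of regulators; miRNA regulators are ranked by
   out-degree with all ties at the cutoff included, and coverage is reported
   as % of distinct circuit targets.
5. **Enrichment** — hypergeometric over-representation analysis of circuit
   gene/miRNA sets against user-supplied GMT collections, BH-adjusted per
   category.
6. **Clinical associations** — per-hub ROC/AUC (tumor vs normal, with the
   standard excellent/good/fair/poor/failure bands), Kruskal–Wallis and
   pairwise Mann–Whitney across pathologic T stages, Kaplan–Meier/log-rank on
   lower- vs upper-quartile expression groups, and Pearson correlation for
   regulator–target pairs with the inverse-significance gate *p* ≤ 0.05 and
   *r* ≤ −0.3.

The `simulate` module generates all four inputs with known planted effects
(NB counts with planted log2 fold changes, a concordance-controlled protein
table, true and decoy interactions, expression-linked T stage and
proportional-hazards survival), so every stage can be tested against ground
truth.

## Worked example

```bash
python examples/02_circuits_and_hubs.py
```

prints (seed 7, 800 genes / 200 miRNAs, 60 tumors / 15 normals):

```
RRC1: 25 interactions between 14 miRNAs and 23 genes
RRC2: 6 interactions between 6 miRNAs and 5 genes
IRC: 34 interactions between 16 miRNAs and 29 genes

RRC1 target hubs (MCC score = number of regulators):
      hub  mcc_score  n_regulators circuit direction
GENE00263        2.0             2    RRC1      down
GENE00366        2.0             2    RRC1      down
...
RRC1 regulator hubs (out-degree; coverage = % of circuit targets hit):
         hub  out_degree  coverage_pct circuit direction
hsa-mir-0169           4          17.4    RRC1        up
hsa-mir-0184           4          17.4    RRC1        up
...
```

Each circuit line is the (interactions, miRNAs, genes) triple of one
mechanism-typed network; a target hub's MCC score equals its regulator count
because circuits are bipartite; a regulator hitting 4 of 23 distinct RRC1
targets covers 17.4%. Note seven regulator hubs are returned for k = 5: all
regulators tied at the fifth-place out-degree are included.

`examples/03_clinical_associations.py` continues with the clinical layer:

```
GENE00005: AUC = 0.9935 (excellent) over 180 tumors vs 18 normals
T-stage Kruskal-Wallis: H = 32.54, p = 4.02e-07 (n = 180); pairwise T1 vs T4 p = 2.22e-07
quartile groups of 45 vs 45 patients; log-rank chi2 = 7.35, p = 6.69e-03
S(24 months): low = 0.88, high = 0.73
```

A 180-patient cohort yields quartile groups of 45; here the planted hazard
gene discriminates tumors almost perfectly, tracks T stage, and separates
survival between expression quartiles.

A thin CLI mirrors the library (`regcircuit simulate|de|integrate|hubs|enrich|clinical|run`).

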