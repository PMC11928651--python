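# Methods

## Model and procedure

The unit of analysis is a genes × samples matrix of log2(TPM+1) expression
values with per-sample metadata (disease label, age at diagnosis, source
stratum, QC status). Expression is assumed already normalized upstream; the
package performs no re-normalization and treats gene identifiers as opaque
strings — gene lists and gene sets must share the matrix's namespace.

Outlier calling is distribution-free: for one gene and one comparator
cohort, the threshold is `Q75 + m·IQR` with `m = 1.5`, and a focus value is
an outlier when it is **strictly** greater than the threshold ("exceeding"
is read as strict; ties are never calls). Quartiles everywhere use linear
interpolation between order statistics (position `1 + q·(n−1)`, numpy's
default); the same convention is used for the similarity-threshold
percentile, the within-sample highly-expressed percentile and the QC-fail
95th percentile, so a single interpolation oracle checks all of them. For a
Gaussian gene this fence is crossed with probability ≈0.35%, which is the
baseline false-call rate the null-calibration test checks against.

Molecular similarity is the Spearman correlation of two samples' profiles
(average ranks for ties; undefined and reported as absent for a
zero-variance profile). The compendium-wide similarity threshold is the
95th percentile of all pairwise correlations, computed over **unordered**
pairs with self-pairs excluded — the ordered/unordered choice is not
observable in the percentile for a symmetric matrix, unordered is simply
cheaper — or a fixed override (e.g. 0.875) when a threshold is pinned to a
compendium version. Neighbor inclusion is strictly above the threshold.
Ranking ties in the top-k most-correlated list break by lexicographic
sample id for determinism.

Cohort rules: the focus sample is excluded from every comparator cohort
(the threshold must describe the background, not the focus; this also
settles whether the pan-cancer cohort contains the focus — it does not).
Disease matching is exact string equality after case/whitespace
normalization. Cohorts smaller than `min_cohort_size` (default 20; a
quartile of two values is formally defined but statistically meaningless,
and undersized same-disease cohorts are precisely the trigger for curated
substitution) are flagged unusable and contribute no calls, but remain
visible in reports. A sample with missing age is excluded from the
age-filtered pediatric cohort, with a warning.

Gene filters for the pan-cancer space: the zero-expression filter drops a
gene when the fraction of samples at exactly 0 is ≥ the cutoff (0.80); the
variance filter then drops `floor(0.20·G)` of the survivors with the lowest
unbiased (n−1) sample variance, ties broken by gene id. Stage order
matters and is fixed (zero filter first). Pan-disease calling uses the
unfiltered gene list; similarity defaults to the filtered space
(configurable) since rank correlations over mostly-zero genes are
uninformative.

Consensus: a gene called in ≥2 of the four personalized cohorts is an
automated pan-disease finding; called in exactly one, it is a
curation-tier finding. When the same-disease cohort is replaced by a
curated clinically-similar-disease cohort, consensus reachable only through
the substitute is classified as curated (`curated_cohort`), never as
automated. Finding types partition all findings: `both`,
`pan_cancer_only`, `pan_disease_only`, `curated`; curation subtypes are
prioritized curated-cohort > single-cohort > mutation-implicated >
highly-expressed, and a gene already automated is never re-reported as
curated. The within-sample 95th-percentile list is treated as an analyst
review list, not an automated finding source; only its mutation-implicated
members are promoted.

Pathway support is operationalized (the source protocol leaves it to the
analyst) as membership in ≥1 gene set whose overlap with the query (the
automated outlier genes) has Benjamini–Hochberg adjusted upper-tail
hypergeometric p below 0.05, testing against the compendium gene universe
with sets intersected with the universe first.

## Synthetic-data generator

Expression for sample *s* of disease *d* at gene *g* is
`clip(base_g + delta_dg + eps_sg, 0)` with `base ~ U(2,10)` (log2 scale),
disease signatures `delta ~ N(0, 1.5²)` and sample noise
`eps ~ N(0, 1²)`. The shared-within/independent-between signature makes
within-disease Spearman correlation exceed between-disease correlation in
expectation (~0.88 vs ~0.62 at the defaults), giving neighbor discovery and
the top-6 rule real signal. Ages give a requested adult share (pediatric
strictly below 30); the TCGA source stratum is drawn with a strong adult
bias (weight 25:1, mirroring compendia where TCGA is >96% adult and
institutional data are mostly pediatric). About 5% of genes are marked as
the synthetic druggable genome. All randomness flows from one explicit
seed; identical seeds give bit-identical output.

Planting utilities construct the phenomena of interest exactly:
`plant_outliers` sets the focus expression to the background cohort's Tukey
fence plus a chosen effect (so recovery tests have a precise margin);
`plant_cohort_divergent_gene` redraws one gene per age stratum around the
gene's median with unequal spreads (equal medians, wider pediatric IQR);
`generate_version_update_scenario` builds the compendium-update case — a
two-sample same-disease cohort whose top-6 list spans three engineered
related diseases, then 95 added same-disease samples with expression
comparable to the focus, with the similarity threshold overridden at 0.872
to sit between the engineered correlation strata on 3,000 genes.

What the generator does **not** emulate: count-level noise (no negative
binomial read model), gene–gene correlation beyond the disease signature,
batch effects, dropout structure, or realistic disease ontologies. Passing
tests therefore demonstrate the *mechanics* of the protocol — thresholds,
cohort rules, consensus logic, and the directional cohort-composition
phenomena — not its clinical yield on real tumors, which depends on
compendium scale and curation.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for a single CPU: planted-outlier
recovery uses 2,000 genes × 300 samples × 3 diseases × 20 seeds with
effect +2.0; null calibration uses 3,000 genes against a 500-sample cohort
drawn with a high expression floor (U(6,12)) so zero-clipping does not
distort the Gaussian tail; the divergent-gene experiment uses 150 samples
per age stratum; end-to-end fixtures use a few hundred genes and ~120–240
samples with 8 diseases (with few diseases, a large share of sample pairs
is within-disease and the 95th-percentile threshold climbs inside the
within-disease correlation range, which starves the neighbor cohorts —
8 diseases keeps them populated at small n). Recovery precision and recall
are measured over the druggable gene space, the space the pipeline's
automated findings are restricted to.

Determinism: reports are canonical JSON (sorted keys, no timestamps);
outlier calls sort by exceedance margin then gene id; all tie-breaks are
lexicographic; cohort members are sorted before quantile computation so
results are invariant to sample order.

Degenerate inputs: a constant cohort vector gives IQR 0 and threshold equal
to the constant (any strictly larger focus value is a call); zero-variance
profiles yield no similarity value rather than a spurious one; an empty
druggable list annotates every finding non-druggable with a warning; an
empty predefined finding set makes the added-findings percentage undefined
(reported absent, with a warning) rather than dividing by zero.

## Known limitations

Only over-expression is detected (no lower-tail calls, by design of the
protocol). The hypergeometric overlap test treats genes as exchangeable —
no expression-level or gene-length bias correction. Curated cohort
composition and mutation/fusion-implicated gene lists are inputs supplied
by a human, not computed. Batch-effect detection and correction are out of
scope; the compendium is assumed uniformly processed.
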