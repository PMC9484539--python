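# Methods

This note documents the models implemented in cernakit, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter for
reproducing results.

## Expression filtering and normalization

Features are retained when their raw count strictly exceeds
`min_count` (default 5) in at least `ceil(min_sample_frac · n)`
samples (default 20%). The ceiling convention means a 16-sample cohort
needs 4 expressing samples; an alternative published phrasing of the
same rule ("more than four samples") would demand 5 at n = 16 — the
ceiling rule is the one implemented, and the filter is idempotent.

Size factors are median-of-ratios: with geometric means taken over
features positive in every sample, `s_j = median_i (k_ij / gm_i)`.
If no feature is positive everywhere the estimator refuses rather than
silently switching to a pseudocount variant.

The working transform is `log2(k_ij / s_j + 1)`. Regularized-log
transforms shrink per-feature dispersion toward a trend inside a
particular estimator; downstream uses here (correlations, cosine
distances, clustering) require only a variance-reasonable monotone
transform, so the simpler shifted log is the default and the transform
is a named option (`kind="shifted_log"`) so an alternative can be
registered without touching callers.

## Negative-binomial differential expression

Counts are modelled per feature as `k_ij ~ NB(mu_ij, α_i)` with
`log mu_ij = log s_j + β0 + β1·1[tumor]`, i.e. a two-group GLM with
log link and size-factor offsets. Because the group indicator
saturates the design, the MLE separates into one scalar mean per
group, solved by a vectorized Newton iteration on the score equation
`Σ_j (k_j − s_j m)/(1 + α s_j m) = 0` (strictly decreasing in `m`, so
convergence is monotone from the Poisson start). The Wald variance of
`log FC` is `1/I_a + 1/I_b` with `I_g = Σ mu_j/(1 + α mu_j)`. A
cross-check against a generic IRLS GLM fit at the same dispersion is
part of the test suite.

Dispersion is method-of-moments on normalized counts, pooled within
groups (`α = (s²_pooled − μ̄)/μ̄²`, floored at 1e-8). Because α is
estimated, the Wald statistic is referred to a t distribution with
n − 2 degrees of freedom rather than the normal; at 8 vs 8 samples
this keeps the null fraction of p < 0.05 at the nominal 0.05 (the
validation study measures it on 2,000 null features). No dispersion
shrinkage across features, no independent filtering and no fold-change
shrinkage are applied — the test is deliberately the plain NB Wald
stand-in, validated by calibration.

Features with all-zero counts report p = 1, log2FC = 0 and a
`degenerate` flag; a group that is all-zero gets a half-count
continuity correction for the fold change and the same flag.

Dysregulation calls use strict inequalities exactly as printed:
up iff `padj < cut` and `log2FC > log2(fc)`; the tumorigenesis cut is
0.1, the subclass cut 0.25, the fold-change cut 2.

The two-group exosome-style comparison is a two-sided rank-sum test
(mid-rank ties, exact when feasible). The choice of test for that
comparison is not prescribed by the analysis this package follows;
Wilcoxon is the package's default and is so labelled.

## Nearest-template prediction

A template is a signed gene list. For each sample and class, the
sample's expression over the template's genes is standardized (mean 0,
sd 1 across genes) and compared with the sign vector by cosine
distance `d = 1 − cos(z, t) ∈ [0, 2]`; the predicted class minimizes
d. Standardization plus cosine makes the distance invariant to affine
rescaling of the sample vector. Significance is resampling-based:
`n_perm` (default 1,000) random templates of the same size and sign
pattern are drawn from the genes present in the matrix, and
`p = (1 + #{d_rand ≤ d_obs}) / (n_perm + 1)`; FDR is
Benjamini–Hochberg across samples, and calls are confident at
FDR < 0.05. Argmin ties break to the first class in the template list
and are never confident. Templates with under 50% of their genes in
the matrix are an error; zero-variance samples are left unclassified
with a warning. A sample exactly equal to a balanced (equal numbers of
+1/−1) template has distance 0 and the minimal attainable p.

## circRNA origin classification

Junction coordinates are 1-based inclusive internally; BED-like
junction files (0-based half-open) are converted exactly once, at read
time, as are GTF gene models (already 1-based). The decision rule, in
order: **exonic** if both breakpoints lie within `slack` bp of exon
boundaries of one same-strand gene (junction start against exon
starts, junction end against exon ends); else **intronic** if the span
sits strictly inside a single intron; else **intergenic** if no
same-strand gene overlaps. Antisense-only overlap is intergenic
because splice-site annotation is strand-specific. A junction that
overlaps a gene but matches neither rule falls back to exonic when
either breakpoint touches an exon interval (dominant-category
convention), else intronic; fallback calls carry a flag so they can be
audited. `slack` defaults to 0 with ±2 bp available for aligner
wobble. Alternative circularization is summarized as the fraction of
host genes with ≥ k isoforms; k defaults to 2 (the minimal evidence of
more than one circularization event per gene), with k = 3 available
for a strictly-more-than-two reading.

## Seed-site discovery and target filtering

Sites are exact Watson–Crick reverse complements of the miRNA seed
with no G:U wobble. With comp(N_k) the complement of miRNA position k,
a site in target 5'→3' orientation reads comp(N8)..comp(N2) for
7mer-m8, and the A1 variants add an A immediately 3' of the core (an
identity requirement, not a pairing). Strict mode — the default, and
the only mode used by the pipeline — reports 7mer-m8 and 8mer only.
Site positions are 1-based; m8-anchored types start at the m8-pairing
base. A brute-force window scanner serves as the oracle in tests, and
the strict-site rate on random sequence matches the analytic 4⁻⁷ per
window. Full hybridization scoring and free-energy filtering are out
of scope; externally computed site lists can be substituted for the
seed scan when a thermodynamic predictor's output is available.

Candidate pairs combine seed sites on ncRNA sequences with external
mRNA–miRNA tables (validated and predicted dialects normalized to one
schema; duplicates across sources collapse with merged evidence).
Pairs must be dysregulated in opposite directions, and their Pearson
correlation across **all** samples (tumor + normal, transformed scale)
must be ≤ −0.4. The boundary is inclusive ("threshold at −0.4");
exclusive behavior is a config switch. The correlation filter is
applied to database-derived mRNA pairs as well as to seed-derived
ncRNA pairs.

## ceRNA network assembly

For a sponge (lncRNA or circRNA) targeted by K miRNAs and an mRNA
targeted by n, sharing k within a universe of N, the one-sided
hypergeometric tail `P(X ≥ k)` is computed through scipy's log-space
survival function (exact against enumeration to N = 12 in the tests,
and well-behaved at the 1e-6 tail). An edge requires all three
criteria with strict inequalities: k > 4, p < 1e-6, sponge–mRNA
PCC > 0.6.

The universe N defaults to all detected miRNAs in the expression
matrix. The choice matters: a universe restricted to the miRNAs
surviving the pair filters (a few dozen in a typical run) makes even a
complete 5–6-miRNA overlap arithmetically incapable of reaching the
1e-6 cut (e.g. k=K=n=6 needs N ≳ 45 for `1/C(N,6) < 1e-6`), starving
the test of resolution; published shared-sponge analyses that report
such overlaps as significant are implicitly referencing the detected
or annotated miRNA space. The conservative tested-space alternative
remains available (`universe="pairs"`), as does an explicit set. No
multiple-testing correction is applied to the hypergeometric p — the
raw cut is the criterion — but a BH column is emitted for
transparency. Edges are sorted by p then ids, so assembly is invariant
to input order.

Cis-regulation candidates (`cis_pairs`) are ncRNA–gene neighbors
within `max_distance` bp (default 10 kb, interval gap) with PCC
strictly above 0.8.

## Co-expression GSEA

The ranking metric is Pearson correlation with the query feature
across all samples, sorted descending with lexicographic tie-break.
The enrichment score is the classic weighted Kolmogorov–Smirnov
running sum: hits add `|score|^p / Σ_set |score|^p` (p = 1 by
default), misses subtract `1/(N − N_hit)`; ES is the signed maximum
deviation, always in [−1, 1]. The extremum takes the earliest index
within 1e-12 of the maximum absolute deviation, making ties
deterministic. The leading edge is the set genes at or before the
extremum for positive ES and at or after it for negative ES.

The null permutes gene sets (random same-size sets from the ranked
universe), the standard preranked convention — phenotype permutation
is undefined when the ranking is a correlation with a single feature.
The nominal p is estimated from the same-sign portion of the null with
add-one smoothing in numerator and denominator, which keeps null
p-values uniform (verified by KS over 200 replicate rankings);
NES = ES / mean(same-sign null |ES|); FDR follows the sign-stratified
null-ratio convention, capped at 1. Sets with fewer than `min_size`
(default 5) genes in the ranking are skipped with a warning.

## Survival analysis

Kaplan–Meier estimation and Cox regression are delegated to lifelines
(Efron tie handling, Newton–Raphson partial likelihood, Wald p). The
G-rho family is implemented directly: at each distinct event time the
observed-minus-expected events in group 1 are weighted by
`Ŝ(t−)^ρ` from the pooled Kaplan–Meier left limit, with the usual
hypergeometric variance; ρ = 0 reproduces the log-rank test exactly
(checked against a hand-tabulated 6-subject fixture and an independent
implementation). The prognostic screen reports, per feature, the
univariate Cox Wald p (the normative criterion, significant at
α = 0.05) and a median-split G-rho p for the matching KM display; the
median cut is the package's choice where no dichotomization rule is
prescribed. Intersecting the survival screen with a good-vs-poor
differential expression contrast (FDR < 0.05, fold change > 2) is a
thin set operation in the pipeline driver.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
with full truth labels:

* **Counts**: `k_ij ~ NB(2^{L_ij} · s_j, α)` with per-sample size
  factors `s_j ~ lognormal(0, 0.2)` (so normalization is non-trivial),
  baseline log2 means uniform on [5, 9] (≈ 30–500 counts), and
  dispersion α = 0.1 — a typical bulk RNA-seq magnitude chosen for
  testability; no dispersion–mean trend is modelled.
* **Dysregulation**: a fraction (default 10%) of each biotype gets a
  ±2 log2-unit tumor shift. With `de_fraction = 0` nothing is planted
  and the truth set is empty.
* **Sponge modules**: each module couples one sponge (lncRNAs and
  circRNAs alternating), 6 miRNAs and one mRNA through a shared
  standard-normal latent factor on the log2-mean scale, loading
  +`sponge_effect` on sponge and mRNA and −`sponge_effect` on the
  miRNAs — the simplest mechanism producing the sign pattern the ceRNA
  filters assume. Module members are also planted as dysregulated
  (sponge and mRNA up, miRNAs down) so they survive the
  opposite-direction rule. Presets: 0.4 / 0.8 / 1.2 (low, default,
  high); at the high preset an expression PCC of roughly ±0.9 results.
  The default miRNA feature count (600, giving ~120 dysregulated
  miRNAs at the default DE fraction) mirrors the scale of dysregulated
  miRNA catalogs in the tumor cohorts this pipeline targets.
* **Subclasses**: signed signature genes (default 30 per class)
  shifted by ±2 log2 units in the member samples; the signed templates
  are returned as truth.
* **Survival**: tumor samples carry a standard-normal prognostic
  score; a few lncRNAs (default 5) are shifted proportionally to it,
  and event times are Weibull (shape 1.5, scale 60 time units) with
  log hazard linear in the score (slope 0.7). Censoring: with
  probability `censor_rate` the observation is replaced by a uniform
  fraction of the event time, so the expected censoring fraction
  equals the configured rate exactly.
* **Sequences**: random-background RNA (miRNAs 22 nt, targets
  400 nt); each planted (sponge, miRNA) and (mRNA, miRNA) relation
  receives one exact seed-complement insertion at spaced offsets, so
  every planted site is recoverable and chance background sites occur
  at the analytic rate.
* **Annotation**: non-overlapping multi-exon gene models on one
  synthetic chromosome and junctions drawn in configurable
  exonic/intronic/intergenic proportions (default 85.82 / 7.18 / 7.0%,
  the dominant-exonic split typical of back-splice catalogs).

What the generator does **not** emulate: dispersion–mean trends, GC
and length biases, correlated gene programs beyond the planted
modules, isoform-level quantification noise, paired-sample
correlation (pairing is recorded in metadata but counts are drawn
independently, matching the two-group design of the DE model), batch
effects, or realistic genome structure (overlapping and antisense
genes). Passing the recovery studies therefore demonstrates the
correctness and calibration of the algorithms under their stated
assumptions, not performance on real cohorts.

## Validation study sizes

The reference validation conditions (tests and
`scripts/acceptance.py`) are: exhaustive hypergeometric check to
N = 12; 1,000 random miRNA/target pairs for the seed oracle; 2,000
features at 8 vs 8 for DE calibration; a 32-pair cohort at the high
sponge preset for network recovery (with a per-feature
sample-permuted negative control); 8-pair recovery and a 30-tumor
null cohort for NTP; 500 random instances and 200 replicate rankings
for GSEA; n = 300 for Cox slope recovery and 100 null features for
the survival screen; 400 junctions for origin agreement; and two full
pipeline runs for byte-identical determinism.

## Known limitations

* The NB test is a calibrated stand-in, not a reimplementation of any
  specific DE package; on real data with strong dispersion trends a
  shrinkage estimator will be more powerful.
* Strict seed matching ignores pairing thermodynamics, conservation
  and 3'-compensatory sites; it bounds, rather than reproduces, a full
  target predictor's output (a hook accepts external site lists).
* Marginal Pearson correlation is the only co-expression measure;
  no partial-correlation or mediation-style sponge scoring.
* The hypergeometric universe is a modelling choice; both supported
  definitions are reported in the edge records (N is stored per edge).
* NTP significance assumes exchangeability of genes under the null;
  heavily correlated signature genes make the resampled null
  conservative.
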