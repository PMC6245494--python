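# Methods

This note documents the statistical procedures implemented in `survsig`,
the synthetic-cohort generator that the tests and benchmarks run on, the
numerical conventions, and the design choices made where the method left
room for them.

## Survival model

Cox proportional-hazards fits maximize the partial likelihood with
**Efron's tie correction** by Newton–Raphson with step-halving, stopping
when the score's infinity norm falls below 1e-8 (at most 50 iterations).
Wald p-values come from the inverse observed information. Monotone
likelihood (perfect separation) is detected as a coefficient exceeding 10
in magnitude with a standard error larger than the coefficient; the fit is
then flagged non-converged, preserving the sign of the divergence. A
constant feature returns coef = 0, HR = 1, p = 1 with a warning; zero
events is an error. The multivariate fit rejects exactly collinear
columns up front (pivoted QR), naming the dependent columns. The
implementation is cross-checked in the test suite against lifelines and
against grid-search maximization of an independently coded partial
likelihood.

**Concordance index.** A pair (i, j) is comparable iff the member with the
smaller observed time had the event; pairs with tied times are not
comparable. Concordant pairs score 1, tied risk scores 0.5. With no
comparable pairs the index is 0.5 by convention. This convention is fixed
because published analyses rarely state their C-index variant; it matches
Harrell's C without a tied-time credit.

**Kaplan–Meier and log-rank** are delegated to lifelines; curves are
reported at the distinct event times, prepended with (t=0, S=1).

## Risk stratification

Features are min-max normalized per feature, (g − min)/(max − min); a
constant feature maps to all-zeros (kept, not dropped, so feature indices
stay stable for GA chromosomes). Samples are clustered by k-means with
k = 2, k-means++ initialization, 10 restarts and a fixed seed. The cluster
with the higher event fraction is labeled high-risk; ties go to the
cluster with the shorter mean observed time. The reported C-index is the
concordance of the high/low indicator itself — identical to the fitted Cox
linear predictor's concordance whenever the fitted coefficient is positive
(the typical case given the labeling rule), and guaranteeing the clean
symmetry that swapping labels maps C to 1 − C and HR to 1/HR.

## Gene selection

The differential-expression screen is a per-gene Welch t-test on
log₂(x+1) values with Benjamini–Hochberg adjustment, gated at adjusted
p < 0.01 and |log₂FC| > 2 (strict). It deliberately replaces a
negative-binomial count model: the pipeline's contribution is downstream
of DE, and the gate semantics (effect size + adjusted p) are preserved.
An externally computed DE table with the same schema can be substituted
via the pipeline config (`de_table_path`).

Univariate gates are strict inequalities: p < 0.05, and for the sharpened
signature HR > 1.221. The HR gate keeps only harmful-direction features;
this asymmetry is intentional and applies identically to expression and
mutation-derived features.

**Genetic algorithm.** Chromosomes are 0/1 vectors over the candidate
genes; fitness is 1 − C-index of the cluster-then-Cox model built from the
selected columns, with the clustering seed held fixed inside the fitness
function so fitness is a deterministic function of the chromosome (and can
be cached). Defaults: population 200, 100 generations, per-bit mutation
0.01, 20% elitism, rank-based roulette selection, single-point crossover.
Elitism makes the best fitness non-increasing; the best-ever individual is
returned. An all-zero chromosome scores the sentinel worst fitness 1.0.
Callers can inject known subsets into the initial population; the
orchestrated pipeline injects the full candidate set and the HR-filtered
subset, so the GA result provably dominates both. Because the in-sample
C-index landscape over subsets is nearly flat, the search should be read
as an optimizer of predictive concordance, not as a recovery device for
the "true" gene list: on synthetic cohorts it reliably finds subsets that
dominate the planted oracle set's empirical fitness while overlapping it
only partially.

## Mutation analytics

Per-group mutation rates count a patient once per gene. MRDS is
(R_high/R_low)·exp(R_high−R_low); R_low = 0 with R_high > 0 gives +inf
(ranked above all finite scores), both rates 0 gives NaN (excluded from
rankings); ties in the top-k ranking break lexicographically by gene name.
On sparse cohorts the +inf sentinel means genes mutated in a handful of
high-risk patients and no low-risk patients flood the top of the ranking;
a top-k cut must be wide enough to reach past this flood, and rate
differentials are realistically detectable only for recurrently mutated
genes (the generator's `diff_mut_min_base_rate` exists to emulate such
driver-like genes).

SNV spectra keep all 12 strand-resolved substitution types (C>G and G>C
are distinct). Fractions are computed per sample over that sample's SNVs,
so the group comparison is a Welch t-test over per-sample observations;
samples without SNVs are excluded from the test.

Pairwise patterns use the natural-log odds ratio of the 2×2 co-mutation
table with no continuity correction (both = 0 gives −inf); significance is
a two-sided Fisher exact test, BH-adjusted across the tested pairs, with
the tendency (mutual exclusivity vs. co-occurrence) called by the log-OR
sign at adjusted p < 0.05. The cohort denominator (`total_samples`) is an
explicit parameter, since published tables do not always match the stated
cohort size.

## Functional gene-set features

Over-representation of the top differentially mutated genes in each gene
set is tested with the hypergeometric upper tail P[X ≥ overlap] against a
configurable universe (default: all genes observed mutated), BH-adjusted
across sets, gated at raw p < 0.05. Each significant set becomes one 0/1
patient feature (1 iff the patient has a mutation in any member gene).

For the combined model, binary features are rescaled per column to the
mean standard deviation of the min-max-normalized expression columns
before the joint k-means. A raw 0/1 column has sd ≈ 0.5 while a normalized
expression column typically spreads ≈ 0.2, so unscaled binary features
dominate the Euclidean geometry and a single weakly informative set
feature can override the entire expression signature; variance matching
restores the intended "expression signature plus mutation refinements"
semantics. This scaling is configurable (`scale_binary=False` gives plain
concatenation).

## Synthetic cohorts

The generator emulates the data structure the pipeline assumes, with a
ground-truth registry for every planted signal. Per cohort:

- **Latent risk** z ~ N(0,1) per patient; the upper half is the true
  high-risk group.
- **Expression**: log₂-scale background N(μ_g, 1) with μ_g ~ U(3, 8),
  clipped at 0; the planted risk genes add `risk_gene_effect` (default
  1.0 log₂ units) × z. Optionally matched normal samples are drawn from
  the same background and a slice of genes is shifted by `de_log2fc` in
  tumors, giving the DE screen a test surface.
- **Survival**: event times are exponential with hazard
  h₀·exp(β·z) (constant baseline hazard — the simplest law consistent with
  the proportional-hazards model the pipeline fits; default h₀ = 1/1000
  per day, β = 1). Censoring is an independent uniform time on [0, T_max]
  with T_max solved by bisection so the realized censoring fraction hits
  the target (default 0.7) — administrative censoring in expectation.
- **Mutations**: per-gene base rates are log-normal with median 0.48% and
  log-sd 1.25, truncated at 0.33, reproducing a heavy-tailed rate
  distribution whose median sits near 0.5% while the most-mutated genes
  reach ~30%. Planted differential genes have their rate multiplied by
  `diff_mut_effect` (default 2.5) in the true high-risk half; the default
  cap and effect satisfy effect × max rate ≤ 1. Each mutation is an SNP
  (95%) with a 12-type substitution label — the high-risk group's C>G and
  G>C probabilities are raised by `snv_cg_shift` (default 0.05) — or an
  indel (5%).
- **Gene sets**: 30 random sets of 10–30 genes, of which 3 planted sets
  draw half their members from the differential genes.

What the generator does **not** emulate: co-expression/linkage structure
between genes, co-mutation dependence beyond the shared group effect
(pairwise mutual-exclusivity tendencies are therefore absent from
synthetic cohorts and that code path is validated against published count
tables instead), read-level noise, copy number, and non-proportional
hazards. Passing tests on synthetic cohorts therefore demonstrate correct
implementation and calibration of the statistical machinery, not clinical
performance on real tumors.

## Benchmarks and problem sizes

The standard recovery benchmark simulates cohorts of 400 patients × 50
candidate genes with 10 planted risk genes and 10 planted differential
mutation genes (β = 1.0) and runs the realistic path: univariate screen →
k-means grouping → MRDS/enrichment → filtered binary features →
expression-only vs. combined model, over a 20-seed sweep. These sizes keep
a full sweep around a minute while leaving the planted effects clearly
detectable; the demonstration cohort in `analysis/` is larger
(400 × 2000 genes) to give the SNV-spectrum and enrichment stages
realistic mutation density.

## Known limitations

- The DE stand-in ignores library-size normalization and count dispersion;
  feed in an external DE table for count data.
- MRDS has no variance stabilization: its ranking on genes with very few
  mutated patients is dominated by the ±inf sentinels (see above).
- The GA optimizes in-sample concordance and will overfit it; a held-out
  cohort (see `apply_signature`) is the honest measure of a signature.
- k-means with k = 2 assumes two roughly spherical groups in feature
  space; strongly non-elliptical risk structure would need a different
  clustering.
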