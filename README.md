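# survsig

Survival signatures for tumor cohorts from gene expression and somatic
mutations.

Predicting which cancer patients carry a high risk of death from their
molecular profiles is a central problem in clinical genomics. Expression
signatures alone stratify breast-cancer cohorts only moderately well, and
the most frequently mutated genes are not necessarily the most prognostic.
`survsig` implements a pipeline that couples the two data types: it screens
genome-wide expression for survival-associated genes, optimizes a gene
subset with a genetic algorithm, stratifies patients into high/low risk
groups by k-means, quantifies how differently genes are mutated between
those groups, and converts mutation-enriched functional gene sets into
extra binary patient features for a combined survival model. A
synthetic-cohort generator with known ground truth makes every stage
testable without any data download.

The package is aimed at computational biologists who want a reproducible,
fully scripted version of this analysis style — either to run on their own
genes × samples expression tables, clinical follow-up tables, MAF mutation
files and GMT gene-set collections, or to study the statistical behavior of
the method itself on simulated cohorts.

## The model

**Risk stratification.** Each feature is min-max normalized,
g'ᵢⱼ = (gᵢⱼ − minⱼ gᵢⱼ)/(maxⱼ gᵢⱼ − minⱼ gᵢⱼ), and samples are clustered
with k-means (k = 2). The cluster with the higher event fraction is the
high-risk group. A Cox proportional-hazards model is fitted on the binary
group indicator (partial likelihood with Efron tie handling, maximized by
Newton–Raphson in-package), and the grouping is scored with Harrell's
concordance index

> C = P(riskᵢ > riskⱼ | patient i died before patient j),

counting a pair as comparable iff the member with the smaller observed time
had the event, and crediting tied risk scores 0.5. Kaplan–Meier curves and
the two-group log-rank test summarize the separation.

**Gene selection.** Genes pass a differential-expression gate (Welch t on
log₂(x+1), Benjamini–Hochberg adjusted p < 0.01 and |log₂FC| > 2), then a
univariate Cox gate (p < 0.05), optionally sharpened to hazard ratio
HR = exp(β) > 1.221. A genetic algorithm (0/1 chromosome over the
candidate genes, fitness = 1 − C-index of the resulting risk model,
elitism + rank-roulette selection + single-point crossover + per-bit
mutation) searches for the subset maximizing the C-index.

**Mutation analytics.** For each gene, the per-group mutation rate R is the
fraction of the group's patients carrying ≥1 mutation in it, and the
mutation-rate differential score is

> MRDS = (R_high / R_low) · exp(R_high − R_low).

Per-sample 12-type SNV substitution spectra (strand-resolved, so C>G and
G>C are distinct) are compared between groups with Welch t-tests. Pairs of
recurrently mutated genes are tested for mutual exclusivity /
co-occurrence via the natural-log odds ratio of their 2×2 co-mutation table
and a two-sided Fisher exact test with BH adjustment. Gene sets enriched
(hypergeometric, p < 0.05) for the top differentially mutated genes become
binary patient features (1 iff the patient has a mutation in any member
gene), which are filtered by the univariate gate and concatenated with the
expression signature for the combined model.

## Worked example

The numbered drivers under `analysis/` run the whole chain on a simulated
cohort of 400 tumors × 2000 genes (15 planted risk genes, 40 planted
differentially mutated genes, 60 matched normals):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_differential_expression.py
...
python analysis/09_recovery_benchmark.py
```

Output of the run recorded in this repository:

```
02: 40 of 2000 genes pass the DE gate
    planted risk genes among them: 15 of 15
03: 16 of 40 DE genes significant in univariate Cox (p<0.05); 16 also have HR>1.221
    planted risk genes recovered: 15 of 15 (broad), 15 (HR-filtered)
04: GA selected 7 of 16 candidate genes; best fitness 0.2755 (C-index 0.7245)
06: C>G: high 0.125 vs low 0.083, p = 7.00e-10
    G>C: high 0.117 vs low 0.084, p = 1.96e-06
08: signature transfers with C-index 0.6684 (training 0.7245); 7 of 7 genes present
09: risk grouping matches the true groups for >=80% of samples in 100% of seeds
    combined model within 0.01 of expression-only C-index in 95% of seeds
    (mean C: expression 0.6553, combined 0.6565)
```

Reading the numbers: the DE + Cox gates recover every planted risk gene;
the GA trims the candidate set to 7 genes and raises the in-sample C-index
to 0.72; the high-risk group shows the planted excess of C>G and G>C
substitutions; the signature loses only ~0.06 C-index on an independent
replicate cohort; and across 20 seeds the combined expression + mutation
model matches or slightly beats the expression-only model, with the risk
grouping agreeing with the planted truth for ~89% of samples.

The same stages are exposed as a CLI (`survsig simulate|diffexpr|risk|
ga-select|mutpat|features|run-all|apply-signature`) and as a single
orchestrated run (`survsig run-all --config pipeline.yaml`), which writes
every intermediate table plus a manifest with content hashes.

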