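"""Synthetic tumor cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* log2-scale expression with a planted subset of risk genes whose values
  track a latent per-patient hazard score;
* proportional-hazards survival times (constant baseline hazard, i.e.
  exponential) with independent uniform right-censoring calibrated to a
  target censoring fraction;
* sparse per-patient gene mutations with heavy-tailed per-gene rates
  (log-normal, median ~0.5%, a few genes approaching ~30%) and planted
  rate differences between the true high- and low-risk halves;
* 12-type SNV substitution labels with the C>G / G>C fractions shifted
  upward in the high-risk group;
* gene-set collections in which a few planted sets over-sample the
  differentially mutated genes.

Optionally a matched normal-tissue expression matrix is emitted, with a
subset of genes shifted in tumors, so the differential-expression screen
has a test surface.  Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    MutationRecord,
    SurvivalTable,
    write_clinical,
    write_expression,
    write_gmt,
    write_maf,
)
from .mutation import SNV_TYPES

#: Baseline (low-risk) 12-type substitution distribution, strand-resolved.
BASE_SNV_PROBS = {
    "C>T": 0.20, "G>A": 0.20,
    "C>G": 0.08, "G>C": 0.08,
    "C>A": 0.08, "G>T": 0.08,
    "A>G": 0.07, "T>C": 0.07,
    "A>T": 0.04, "T>A": 0.04,
    "A>C": 0.03, "T>G": 0.03,
}


@dataclass
class CohortSpec:
    """Parameters of one simulated cohort.

    ``mut_rate_distribution`` is (median, log-sd, max): per-gene mutation
    rates are log-normal with the given median and log-scale sd, truncated
    at the max.  ``diff_mut_effect`` is the rate ratio applied to the
    planted differentially mutated genes in the high-risk half.
    """

    n_samples: int = 500
    n_genes: int = 2000
    n_risk_genes: int = 20
    hazard_beta: float = 1.0  # log-hazard per unit latent risk (z-score)
    censor_rate: float = 0.7
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    mut_rate_distribution: tuple[float, float, float] = (0.0048, 1.25, 0.33)
    n_diff_mut_genes: int = 20
    diff_mut_effect: float = 2.5
    #: floor on the planted diff-mut genes' base rate (0 = same law as the
    #: rest); raising it emulates recurrently mutated driver genes, which
    #: are the ones whose rate differentials are detectable
    diff_mut_min_base_rate: float = 0.0
    snv_cg_shift: float = 0.05
    n_gene_sets: int = 30
    n_planted_sets: int = 3
    planted_set_enrichment: float = 0.5
    risk_gene_effect: float = 1.0  # expression shift (log2 units) per unit risk
    expression_noise_sd: float = 1.0
    indel_fraction: float = 0.05
    n_normal_samples: int = 0
    n_de_genes: int = 0
    de_log2fc: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_risk_genes", "n_gene_sets"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_risk_genes > self.n_genes:
            raise ValueError("n_risk_genes must not exceed n_genes")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must lie in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        median, sd, max_rate = self.mut_rate_distribution
        if not (0 < median <= max_rate <= 1):
            raise ValueError("mutation rate law needs 0 < median <= max <= 1")
        if self.diff_mut_effect * max_rate > 1.0:
            raise ValueError(
                "infeasible spec: diff_mut_effect x maximum base rate exceeds 1"
            )
        if not 0.0 <= self.diff_mut_min_base_rate <= max_rate:
            raise ValueError("diff_mut_min_base_rate must lie in [0, max rate]")
        if self.n_risk_genes + self.n_diff_mut_genes > self.n_genes:
            raise ValueError("risk and diff-mut gene slices exceed n_genes")
        if self.n_de_genes and self.n_de_genes < self.n_risk_genes:
            raise ValueError("planted risk genes must be a subset of the DE genes")


@dataclass
class GroundTruth:
    risk_gene_ids: list[str]
    latent_risk: pd.Series  # index = sample_id
    true_group: pd.Series  # "high" / "low"
    diff_mut_gene_ids: list[str]
    planted_set_names: list[str]
    de_gene_ids: list[str] = field(default_factory=list)


@dataclass
class SimulatedCohort:
    expression: ExpressionMatrix
    survival: SurvivalTable
    mutations: list[MutationRecord]
    gene_sets: GeneSetCollection
    truth: GroundTruth
    normal_expression: Optional[ExpressionMatrix] = None


def _censor_horizon(event_times: np.ndarray, target: float) -> float:
    """Uniform-censoring horizon T_max such that the expected censored
    fraction (mean of min(T_i/T_max, 1)) hits the target, by bisection."""
    lo, hi = 1e-9, float(event_times.max()) * 1e6

    def frac(tmax: float) -> float:
        return float(np.minimum(event_times / tmax, 1.0).mean())

    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Draw one cohort from the spec; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(1, spec.n_genes + 1)]
    samples = [f"S{i:04d}" for i in range(1, spec.n_samples + 1)]
    risk_genes = genes[: spec.n_risk_genes]
    diff_genes = genes[spec.n_risk_genes : spec.n_risk_genes + spec.n_diff_mut_genes]
    de_genes = genes[: spec.n_de_genes] if spec.n_de_genes else []

    # latent risk and true groups (upper half of the latent score is "high")
    z = rng.standard_normal(spec.n_samples)
    high = z > np.median(z)
    true_group = pd.Series(np.where(high, "high", "low"), index=samples)

    # expression: log2-scale background + planted risk-gene shift
    mu = rng.uniform(3.0, 8.0, size=spec.n_genes)
    expr = mu[:, None] + rng.normal(
        0.0, spec.expression_noise_sd, size=(spec.n_genes, spec.n_samples)
    )
    expr[: spec.n_risk_genes] += spec.risk_gene_effect * z[None, :]
    np.clip(expr, 0.0, None, out=expr)
    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=genes, columns=samples), unit_tag="log2"
    )

    normal_expression = None
    if spec.n_normal_samples:
        normal_ids = [f"N{i:04d}" for i in range(1, spec.n_normal_samples + 1)]
        nexpr = mu[:, None] + rng.normal(
            0.0, spec.expression_noise_sd, size=(spec.n_genes, spec.n_normal_samples)
        )
        np.clip(nexpr, 0.0, None, out=nexpr)
        # the planted DE genes are shifted in tumors relative to normals
        expr[: spec.n_de_genes] += spec.de_log2fc
        np.clip(expr, 0.0, None, out=expr)
        expression = ExpressionMatrix(
            pd.DataFrame(expr, index=genes, columns=samples), unit_tag="log2"
        )
        normal_expression = ExpressionMatrix(
            pd.DataFrame(nexpr, index=genes, columns=normal_ids), unit_tag="log2"
        )

    # survival: exponential PH times + uniform censoring at target rate
    hazard = spec.baseline_hazard * np.exp(spec.hazard_beta * z)
    event_time = rng.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        tmax = _censor_horizon(event_time, spec.censor_rate)
        censor_time = rng.uniform(0.0, tmax, size=spec.n_samples)
        observed = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        observed = event_time
        event = np.ones(spec.n_samples, dtype=int)
    survival = SurvivalTable(
        pd.DataFrame(
            {"sample_id": samples, "time_days": observed, "event": event}
        )
    )

    # mutations: heavy-tailed per-gene rates, planted group differences
    median, log_sd, max_rate = spec.mut_rate_distribution
    base_rate = np.minimum(
        np.exp(rng.normal(math.log(median), log_sd, size=spec.n_genes)), max_rate
    )
    diff_slice = slice(spec.n_risk_genes, spec.n_risk_genes + spec.n_diff_mut_genes)
    if spec.diff_mut_min_base_rate > 0:
        base_rate[diff_slice] = np.maximum(
            base_rate[diff_slice], spec.diff_mut_min_base_rate
        )
    rate = np.tile(base_rate[:, None], (1, spec.n_samples))
    rate[diff_slice, :][:, high] *= spec.diff_mut_effect
    mutated = rng.random((spec.n_genes, spec.n_samples)) < rate

    # substitution-type distributions per group
    base_probs = np.array([BASE_SNV_PROBS[t] for t in SNV_TYPES])
    high_probs = base_probs.copy()
    cg, gc = SNV_TYPES.index("C>G"), SNV_TYPES.index("G>C")
    high_probs[cg] += spec.snv_cg_shift
    high_probs[gc] += spec.snv_cg_shift
    others = np.ones(len(SNV_TYPES), dtype=bool)
    others[[cg, gc]] = False
    high_probs[others] *= (1.0 - high_probs[cg] - high_probs[gc]) / high_probs[others].sum()

    mutations: list[MutationRecord] = []
    gene_idx, sample_idx = np.nonzero(mutated)
    for gi, si in zip(gene_idx, sample_idx):
        sample = samples[si]
        if rng.random() < spec.indel_fraction:
            if rng.random() < 0.5:
                rec = MutationRecord(sample, genes[gi], "DEL", "ACT", "-")
            else:
                rec = MutationRecord(sample, genes[gi], "INS", "-", "TG")
        else:
            probs = high_probs if high[si] else base_probs
            t = SNV_TYPES[rng.choice(len(SNV_TYPES), p=probs)]
            ref, alt = t.split(">")
            rec = MutationRecord(sample, genes[gi], "SNP", ref, alt)
        mutations.append(rec)

    # gene sets: planted sets over-sample the differentially mutated genes
    gene_sets = GeneSetCollection()
    planted_names = []
    other_genes = [g for g in genes if g not in set(diff_genes)]
    for i in range(spec.n_gene_sets):
        size = min(int(rng.integers(10, 31)), spec.n_genes)
        if i < spec.n_planted_sets and diff_genes:
            n_diff = min(int(round(size * spec.planted_set_enrichment)), len(diff_genes))
            n_other = min(size - n_diff, len(other_genes))
            members = list(rng.choice(diff_genes, size=n_diff, replace=False))
            members += list(rng.choice(other_genes, size=n_other, replace=False))
            name = f"SET_PLANTED_{i + 1:02d}"
            planted_names.append(name)
        else:
            members = list(rng.choice(genes, size=size, replace=False))
            name = f"SET_RANDOM_{i + 1:02d}"
        gene_sets.add(name, "synthetic gene set", members)

    truth = GroundTruth(
        risk_gene_ids=risk_genes,
        latent_risk=pd.Series(z, index=samples),
        true_group=true_group,
        diff_mut_gene_ids=diff_genes,
        planted_set_names=planted_names,
        de_gene_ids=de_genes,
    )
    return SimulatedCohort(
        expression, survival, mutations, gene_sets, truth, normal_expression
    )


def summarize_cohort(cohort: SimulatedCohort) -> dict:
    """Cohort-level summary: mutation-rate distribution, event fraction,
    pooled SNV-type fractions."""
    n = len(cohort.expression.sample_ids)
    carriers: dict[str, set[str]] = {}
    for m in cohort.mutations:
        carriers.setdefault(m.gene, set()).add(m.sample_id)
    rates = pd.Series(
        {g: len(s) / n for g, s in carriers.items()}, dtype=float
    ).reindex(cohort.expression.gene_ids, fill_value=0.0)
    snv_counts = pd.Series(0, index=list(SNV_TYPES), dtype=float)
    for m in cohort.mutations:
        if m.variant_type == "SNP":
            snv_counts[f"{m.ref_allele}>{m.alt_allele}"] += 1
    total_snv = snv_counts.sum()
    return {
        "gene_mutation_rates": rates,
        "median_mutation_rate": float(rates[rates > 0].median()) if (rates > 0).any() else 0.0,
        "max_mutation_rate": float(rates.max()),
        "event_fraction": float(cohort.survival.events.mean()),
        "snv_type_fractions": snv_counts / total_snv if total_snv else snv_counts,
    }


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort in the package's external formats + ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "clinical": out / "clinical.tsv",
        "mutations": out / "mutations.maf",
        "gene_sets": out / "gene_sets.gmt",
        "ground_truth": out / "ground_truth.tsv",
    }
    write_expression(cohort.expression, paths["expression"])
    write_clinical(cohort.survival, paths["clinical"])
    write_maf(cohort.mutations, paths["mutations"])
    write_gmt(cohort.gene_sets, paths["gene_sets"])
    truth_frame = pd.DataFrame(
        {
            "sample_id": cohort.truth.latent_risk.index,
            "latent_risk": cohort.truth.latent_risk.to_numpy(),
            "true_group": cohort.truth.true_group.to_numpy(),
        }
    )
    with paths["ground_truth"].open("w") as fh:
        fh.write("# ground truth: per-sample latent risk and true group\n")
        fh.write(f"# risk_genes: {','.join(cohort.truth.risk_gene_ids)}\n")
        fh.write(f"# diff_mut_genes: {','.join(cohort.truth.diff_mut_gene_ids)}\n")
        fh.write(f"# planted_sets: {','.join(cohort.truth.planted_set_names)}\n")
        truth_frame.to_csv(fh, sep="\t", index=False)
    if cohort.normal_expression is not None:
        paths["normal_expression"] = out / "normal_expression.tsv"
        write_expression(cohort.normal_expression, paths["normal_expression"])
    return paths
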