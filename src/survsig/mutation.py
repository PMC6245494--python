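"""Somatic-mutation analytics for high/low survival-risk groups.

Covers per-group gene mutation rates, the mutation-rate differential score

    MRDS_i = (R_high,i / R_low,i) * exp(R_high,i - R_low,i),

top-K ranking by MRDS, 12-type SNV substitution spectra with a per-type
Welch t-test between risk groups, and pairwise mutual-exclusivity /
co-occurrence statistics (2x2 counts, natural-log odds ratio, two-sided
Fisher exact test, BH adjustment).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MutationRecord
from .risk import HIGH, LOW, RiskGrouping
from .diffexpr import bh_adjust

#: The 12 strand-resolved single-nucleotide substitution types.  The strand
#: is deliberately NOT collapsed (C>G and G>C are distinct categories).
SNV_TYPES = tuple(
    f"{ref}>{alt}" for ref in "ACGT" for alt in "ACGT" if ref != alt
)

MUTUAL_EXCLUSIVITY = "mutual_exclusivity"
CO_OCCURRENCE = "co_occurrence"
NO_TENDENCY = "none"


@dataclass
class PairPattern:
    """2x2 co-mutation pattern of an unordered gene pair."""

    gene_a: str
    gene_b: str
    a_not_b: int
    b_not_a: int
    both: int
    neither: int
    log_odds_ratio: float
    p_value: float
    p_adjusted: float = float("nan")
    tendency: str = NO_TENDENCY


def samples_with_mutation(
    mutations: Sequence[MutationRecord],
) -> dict[str, set[str]]:
    """gene -> set of samples carrying at least one mutation in it."""
    out: dict[str, set[str]] = {}
    for m in mutations:
        out.setdefault(m.gene, set()).add(m.sample_id)
    return out


def mutation_rates_by_group(
    mutations: Sequence[MutationRecord], grouping: RiskGrouping
) -> pd.DataFrame:
    """Per-gene mutation rates in the high and low risk groups.

    The rate is the fraction of group members carrying >=1 mutation in the
    gene (a sample counts once per gene regardless of how many variants it
    has there).  Mutations in samples outside the grouping are dropped with
    a warning.
    """
    high_ids = {s for s, l in grouping.labels.items() if l == HIGH}
    low_ids = {s for s, l in grouping.labels.items() if l == LOW}
    if not high_ids or not low_ids:
        raise ValueError("both risk groups must be non-empty")
    known = high_ids | low_ids
    unknown = {m.sample_id for m in mutations} - known
    if unknown:
        warnings.warn(
            f"dropping mutations from {len(unknown)} samples absent from the grouping"
        )
    by_gene = samples_with_mutation([m for m in mutations if m.sample_id in known])
    rows = []
    for gene in sorted(by_gene):
        carriers = by_gene[gene]
        rows.append(
            {
                "gene": gene,
                "r_high": len(carriers & high_ids) / len(high_ids),
                "r_low": len(carriers & low_ids) / len(low_ids),
                "n_high": len(high_ids),
                "n_low": len(low_ids),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "r_high", "r_low", "n_high", "n_low"]).set_index(
        "gene"
    )


def mrds(r_high: float, r_low: float) -> float:
    """Mutation-rate differential score of one gene.

    r_low = 0 with r_high > 0 yields +inf (ranks above all finite scores);
    both rates 0 yields NaN (undefined; excluded from rankings).
    """
    for name, r in (("r_high", r_high), ("r_low", r_low)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name}={r} outside [0, 1]")
    if r_high == 0.0 and r_low == 0.0:
        return float("nan")
    if r_low == 0.0:
        return float("inf")
    return (r_high / r_low) * math.exp(r_high - r_low)


def mrds_scores(rates: pd.DataFrame) -> pd.Series:
    """MRDS per gene from a mutation_rates_by_group table."""
    return pd.Series(
        [mrds(rh, rl) for rh, rl in zip(rates["r_high"], rates["r_low"])],
        index=rates.index,
        name="mrds",
    )


def top_k_by_mrds(rates: pd.DataFrame, k: int = 2000) -> list[str]:
    """Genes sorted by MRDS descending (ties broken by gene name).

    Genes with undefined MRDS (never mutated in either group) are excluded.
    If fewer than k genes have a defined score, all are returned with a
    warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = mrds_scores(rates).dropna()
    if k > len(scores):
        warnings.warn(
            f"requested top {k} genes but only {len(scores)} have defined MRDS"
        )
        k = len(scores)
    ordered = scores.sort_index().sort_values(ascending=False, kind="stable")
    return list(ordered.index[:k])


def snv_spectrum(
    mutations: Sequence[MutationRecord], grouping: RiskGrouping
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample 12-type SNV fractions and a per-type group Welch t-test.

    Only SNP records are used.  Each sample's fractions are computed over
    its own SNVs (so they sum to 1 for samples with any SNV); samples with
    zero SNVs are excluded from the t-test with a warning.  If either group
    has fewer than two SNV-bearing samples the tests are skipped (NaN).
    """
    snvs = [m for m in mutations if m.variant_type == "SNP"]
    labels = grouping.labels
    counts: dict[str, np.ndarray] = {}
    for m in snvs:
        if m.sample_id not in labels.index:
            continue
        row = counts.setdefault(m.sample_id, np.zeros(len(SNV_TYPES)))
        row[SNV_TYPES.index(f"{m.ref_allele}>{m.alt_allele}")] += 1
    fractions = pd.DataFrame(
        0.0, index=labels.index, columns=list(SNV_TYPES)
    )
    for sample, row in counts.items():
        fractions.loc[sample] = row / row.sum()
    with_snv = fractions.index[fractions.sum(axis=1) > 0]
    n_empty = len(labels) - len(with_snv)
    if n_empty:
        warnings.warn(f"{n_empty} samples with no SNVs excluded from the spectrum test")
    high = fractions.loc[[s for s in with_snv if labels[s] == HIGH]]
    low = fractions.loc[[s for s in with_snv if labels[s] == LOW]]
    rows = []
    skip = len(high) < 2 or len(low) < 2
    if skip:
        warnings.warn("a group has <2 SNV-bearing samples; spectrum tests skipped")
    for t in SNV_TYPES:
        if skip:
            stat, p = float("nan"), float("nan")
        else:
            a, b = high[t].to_numpy(), low[t].to_numpy()
            if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "snv_type": t,
                "mean_high": float(high[t].mean()) if len(high) else float("nan"),
                "mean_low": float(low[t].mean()) if len(low) else float("nan"),
                "t_statistic": float(stat),
                "p_value": float(p),
            }
        )
    return fractions, pd.DataFrame(rows).set_index("snv_type")


def pattern_from_counts(
    gene_a: str,
    gene_b: str,
    a_not_b: int,
    b_not_a: int,
    both: int,
    total_samples: int,
) -> PairPattern:
    """Build a pair pattern from its 2x2 counts.

    The log odds ratio is the natural log of (both * neither) /
    (a_not_b * b_not_a), with no continuity correction; both == 0 gives
    -inf.  The p-value is a two-sided Fisher exact test.
    """
    neither = total_samples - a_not_b - b_not_a - both
    if neither < 0:
        raise ValueError("total_samples smaller than the observed counts")
    table = np.array([[both, a_not_b], [b_not_a, neither]])
    num = both * neither
    den = a_not_b * b_not_a
    if num > 0 and den > 0:
        log_or = float(math.log(num) - math.log(den))
    elif num == 0 and den > 0:
        log_or = float("-inf")
    elif num > 0 and den == 0:
        log_or = float("inf")
    else:
        log_or = float("nan")
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return PairPattern(gene_a, gene_b, a_not_b, b_not_a, both, neither, log_or, p)


def pairwise_patterns(
    mutations: Sequence[MutationRecord],
    genes: Sequence[str],
    total_samples: int,
    alpha: float = 0.05,
) -> list[PairPattern]:
    """Mutual-exclusivity / co-occurrence statistics for all gene pairs.

    For each unordered pair, counts samples mutated in exactly one gene,
    both, or neither (out of ``total_samples``), computes the natural-log
    odds ratio and a two-sided Fisher exact p, BH-adjusts across the tested
    pairs, and calls the tendency by the sign of the log OR when adjusted
    p < alpha.  Pairs involving a never-mutated gene are skipped with a
    warning.
    """
    by_gene = samples_with_mutation(mutations)
    patterns: list[PairPattern] = []
    for gene_a, gene_b in itertools.combinations(genes, 2):
        sa, sb = by_gene.get(gene_a, set()), by_gene.get(gene_b, set())
        if not sa or not sb:
            warnings.warn(f"pair ({gene_a}, {gene_b}) skipped: zero margin")
            continue
        both = len(sa & sb)
        patterns.append(
            pattern_from_counts(
                gene_a, gene_b, len(sa) - both, len(sb) - both, both, total_samples
            )
        )
    _adjust_and_call_tendency(patterns, alpha)
    return patterns


def patterns_from_count_table(
    rows: Sequence[tuple[str, str, int, int, int]],
    total_samples: int,
    alpha: float = 0.05,
) -> list[PairPattern]:
    """Pair patterns from pre-tabulated (gene_a, gene_b, a_not_b, b_not_a,
    both) counts, with BH adjustment and tendency calls across the rows."""
    patterns = [
        pattern_from_counts(a, b, an, bn, both, total_samples)
        for a, b, an, bn, both in rows
    ]
    _adjust_and_call_tendency(patterns, alpha)
    return patterns


def _adjust_and_call_tendency(patterns: list[PairPattern], alpha: float) -> None:
    if not patterns:
        return
    adjusted = bh_adjust([p.p_value for p in patterns])
    for pat, padj in zip(patterns, adjusted):
        pat.p_adjusted = float(padj)
        lor = pat.log_odds_ratio
        if padj < alpha and not math.isnan(lor) and lor != 0:
            pat.tendency = CO_OCCURRENCE if lor > 0 else MUTUAL_EXCLUSIVITY


def patterns_to_frame(patterns: Sequence[PairPattern]) -> pd.DataFrame:
    """Tabulate pair patterns in the standard column layout."""
    return pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "a_not_b": p.a_not_b,
                "b_not_a": p.b_not_a,
                "both": p.both,
                "log_odds_ratio": p.log_odds_ratio,
                "p_adjusted": p.p_adjusted,
                "tendency": p.tendency,
            }
            for p in patterns
        ]
    )
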