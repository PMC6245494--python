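"""Mutation analytics per risk group.

Computes per-group gene mutation rates and MRDS ranks, tests the 12-type
SNV substitution spectra between the groups (looking for the planted C>G
/ G>C excess in the high-risk group), and tabulates pairwise mutual
exclusivity / co-occurrence among the most mutated genes.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from common import RESULTS, load_cohort, load_truth, save
from survsig.mutation import (
    mutation_rates_by_group,
    mrds_scores,
    pairwise_patterns,
    patterns_to_frame,
    samples_with_mutation,
    snv_spectrum,
    top_k_by_mrds,
)
from survsig.risk import RiskGrouping

TOP_K = 400
N_TOP_MUTATED = 8


def main() -> None:
    _, survival, mutations, _ = load_cohort()
    labels = pd.read_csv(
        RESULTS / "05_risk_groups.tsv", sep="\t", comment="#", index_col=0
    )["risk_group"]
    grouping = RiskGrouping(labels)

    rates = mutation_rates_by_group(mutations, grouping)
    rates = rates.assign(mrds=mrds_scores(rates))
    save(rates, "06_mutation_rates.tsv", "per-group gene mutation rates + MRDS")
    top = top_k_by_mrds(rates, k=TOP_K)
    _, meta = load_truth()
    planted = set(meta.get("diff_mut_genes", []))
    print(f"top {TOP_K} MRDS genes contain {len(planted & set(top))} of "
          f"{len(planted)} planted differentially mutated genes")

    _, spectrum_tests = snv_spectrum(mutations, grouping)
    save(spectrum_tests, "06_snv_spectrum_tests.tsv",
         "per-type SNV fraction Welch t-tests between risk groups")
    for t in ("C>G", "G>C"):
        row = spectrum_tests.loc[t]
        print(f"{t}: high {row['mean_high']:.3f} vs low {row['mean_low']:.3f}, "
              f"p = {row['p_value']:.2e}")

    by_gene = samples_with_mutation(mutations)
    top_mutated = sorted(by_gene, key=lambda g: (-len(by_gene[g]), g))[:N_TOP_MUTATED]
    total = len({m.sample_id for m in mutations})
    patterns = patterns_to_frame(
        pairwise_patterns(mutations, top_mutated, total)
    )
    save(patterns, "06_pairwise_patterns.tsv",
         "pairwise mutual exclusivity / co-occurrence, top mutated genes",
         index=False)
    called = patterns[patterns["tendency"] != "none"]
    print(f"{len(called)} of {len(patterns)} top-gene pairs show a "
          f"significant tendency")


if __name__ == "__main__":
    main()
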