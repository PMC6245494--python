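"""Build functional gene-set features and the combined survival model.

Enriches the top differentially mutated genes (by MRDS) against the
gene-set collection, turns significant sets into binary per-patient
features, keeps those passing the univariate gate (p < 0.05, HR > 1.221),
and compares the expression-only model with the combined
expression + mutation model.
"""

import dataclasses
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from common import RESULTS, load_cohort, load_truth, save
from survsig.functional import (
    binary_set_features,
    combined_model,
    enrich,
    filter_features_univariate,
    significant_sets,
)
from survsig.mutation import mutation_rates_by_group, samples_with_mutation, top_k_by_mrds
from survsig.risk import RiskGrouping

TOP_K = 400
CLUSTER_SEED = 17


def main() -> None:
    expression, survival, mutations, gene_sets = load_cohort()
    labels = pd.read_csv(
        RESULTS / "05_risk_groups.tsv", sep="\t", comment="#", index_col=0
    )["risk_group"]
    grouping = RiskGrouping(labels)

    rates = mutation_rates_by_group(mutations, grouping)
    query_pool = top_k_by_mrds(rates, k=TOP_K)
    universe = sorted(samples_with_mutation(mutations))
    enrichment = enrich([g for g in query_pool if g in set(universe)],
                        gene_sets, universe)
    save(pd.DataFrame([dataclasses.asdict(r) for r in enrichment]),
         "07_enrichment.tsv", "hypergeometric over-representation per gene set",
         index=False)
    sig = significant_sets(enrichment, gene_sets)
    _, meta = load_truth()
    planted_sets = set(meta.get("planted_sets", []))
    print(f"{len(sig)} of {len(gene_sets)} gene sets enriched (p<0.05); "
          f"planted sets recovered: {len(planted_sets & set(sig.names()))} "
          f"of {len(planted_sets)}")

    candidates = binary_set_features(mutations, expression.sample_ids, sig)
    kept = filter_features_univariate(candidates, survival)
    save(kept, "07_functional_features.tsv",
         "binary set features passing the univariate gate")
    print(f"{kept.shape[1]} of {candidates.shape[1]} set features pass the "
          f"univariate gate (p<0.05, HR>1.221)")

    ga_genes = pd.read_csv(RESULTS / "04_ga_genes.tsv", sep="\t")["gene"].tolist()
    expr_features = expression.subset_genes(ga_genes).frame.T
    empty = pd.DataFrame(index=expr_features.index)
    ev_expr = combined_model(expr_features, empty, survival, seed=CLUSTER_SEED)
    ev_comb = combined_model(expr_features, kept, survival, seed=CLUSTER_SEED)
    report = pd.DataFrame(
        [
            {"model": "expression_only", "n_features": len(ga_genes),
             "c_index": ev_expr.c_index, "hazard_ratio": ev_expr.hazard_ratio,
             "logrank_p": ev_expr.logrank_p},
            {"model": "combined", "n_features": len(ga_genes) + kept.shape[1],
             "c_index": ev_comb.c_index, "hazard_ratio": ev_comb.hazard_ratio,
             "logrank_p": ev_comb.logrank_p},
        ]
    )
    save(report, "07_combined_model.tsv",
         "expression-only vs combined model comparison", index=False)
    print(report.to_string(index=False, float_format=lambda v: f"{v:.4f}"))


if __name__ == "__main__":
    main()
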