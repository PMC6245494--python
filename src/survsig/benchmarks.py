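"""Synthetic-cohort benchmarks of the full modelling chain.

These run the realistic analysis path (univariate screen -> k-means risk
groups -> mutation analytics -> functional features -> combined model) on
generated cohorts with known ground truth and report recovery statistics.
They back the numbered analysis drivers and the acceptance checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .functional import (
    binary_set_features,
    combined_model,
    enrich,
    filter_features_univariate,
    significant_sets,
    univariate_screen,
)
from .mutation import (
    mutation_rates_by_group,
    samples_with_mutation,
    top_k_by_mrds,
)
from .risk import cluster_risk_groups, minmax_normalize
from .synthetic import CohortSpec, simulate_cohort

#: Conditions of the standard recovery experiment: a moderate cohort with a
#: planted expression signature and planted differential mutations.
RECOVERY_SPEC = dict(
    n_samples=400,
    n_genes=50,
    n_risk_genes=10,
    n_diff_mut_genes=10,
    hazard_beta=1.0,
)


@dataclass
class RecoveryResult:
    seed: int
    grouping_agreement: float
    n_selected_genes: int
    n_significant_sets: int
    n_functional_features: int
    c_index_expression: float
    c_index_combined: float


def risk_recovery_run(seed: int, cluster_seed: int = 17, top_k: int = 20,
                      **spec_overrides) -> RecoveryResult:
    """One replicate: simulate, screen, stratify, build mutation features,
    and compare the expression-only and combined risk models against the
    planted truth."""
    params = {**RECOVERY_SPEC, **spec_overrides}
    cohort = simulate_cohort(CohortSpec(seed=seed, **params))
    features = cohort.expression.frame.T
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        screen = univariate_screen(features, cohort.survival)
        selected = screen.index[screen["p_value"] < 0.05].tolist()
        if not selected:  # degenerate draw: fall back to the full panel
            selected = list(features.columns)
        grouping = cluster_risk_groups(
            minmax_normalize(features[selected]), cohort.survival, seed=cluster_seed
        )
        agreement = float((grouping.labels == cohort.truth.true_group).mean())

        rates = mutation_rates_by_group(cohort.mutations, grouping)
        top_genes = top_k_by_mrds(rates, k=top_k)
        universe = sorted(samples_with_mutation(cohort.mutations))
        enrichment = enrich(
            [g for g in top_genes if g in set(universe)],
            cohort.gene_sets,
            universe,
        )
        sig_sets = significant_sets(enrichment, cohort.gene_sets)
        sample_ids = cohort.expression.sample_ids
        if len(sig_sets):
            candidates = binary_set_features(cohort.mutations, sample_ids, sig_sets)
            mut_features = filter_features_univariate(candidates, cohort.survival)
        else:
            mut_features = pd.DataFrame(index=sample_ids)

        expr_features = features[selected]
        empty = pd.DataFrame(index=expr_features.index)
        ev_expr = combined_model(expr_features, empty, cohort.survival, seed=cluster_seed)
        ev_comb = combined_model(
            expr_features, mut_features, cohort.survival, seed=cluster_seed
        )
    return RecoveryResult(
        seed=seed,
        grouping_agreement=agreement,
        n_selected_genes=len(selected),
        n_significant_sets=len(sig_sets),
        n_functional_features=int(mut_features.shape[1]),
        c_index_expression=ev_expr.c_index,
        c_index_combined=ev_comb.c_index,
    )


def risk_recovery_benchmark(
    n_seeds: int = 20, base_seed: int = 0, **spec_overrides
) -> pd.DataFrame:
    """Seed sweep of :func:`risk_recovery_run` as a tidy table."""
    rows = [
        risk_recovery_run(base_seed + i, **spec_overrides).__dict__
        for i in range(n_seeds)
    ]
    return pd.DataFrame(rows)
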