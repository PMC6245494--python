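"""Hypergeometric set enrichment, binary set features, the univariate
feature gate, and the combined expression + mutation model."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from survsig.functional import (
    binary_set_features,
    combined_model,
    enrich,
    filter_features_univariate,
    passes_univariate_gate,
    significant_sets,
)
from survsig.io_formats import GeneSetCollection, MutationRecord
from survsig.risk import minmax_normalize
from survsig.synthetic import CohortSpec, simulate_cohort

from conftest import make_survival


def collection(**sets):
    coll = GeneSetCollection()
    for name, genes in sets.items():
        coll.add(name, "d", genes)
    return coll


def snp(sample, gene):
    return MutationRecord(sample, gene, "SNP", "C", "T")


# --- enrichment -------------------------------------------------------------

def test_enrich_full_overlap_worked_case():
    """Universe 10, set 5, query 5, overlap 5: p = 1/C(10,5) = 1/252."""
    universe = [f"g{i}" for i in range(10)]
    sets = collection(hit=universe[:5])
    (res,) = enrich(universe[:5], sets, universe)
    assert res.overlap == 5
    assert res.p_value == pytest.approx(1 / 252, rel=1e-12)
    assert res.significant


def test_enrich_disjoint_set_p_one():
    universe = [f"g{i}" for i in range(10)]
    sets = collection(miss=universe[5:])
    (res,) = enrich(universe[:3], sets, universe)
    assert res.overlap == 0
    assert res.p_value == pytest.approx(1.0)
    assert not res.significant


def test_enrich_query_equals_universe_saturates():
    universe = [f"g{i}" for i in range(8)]
    sets = collection(a=universe[:4], b=universe[2:7])
    results = enrich(universe, sets, universe)
    for r in results:
        assert r.overlap == r.set_size
        assert r.p_value == pytest.approx(1.0)


def test_enrich_empty_universe_error():
    with pytest.raises(ValueError, match="universe"):
        enrich([], collection(a=["g1"]), [])


def test_enrich_query_outside_universe_error():
    with pytest.raises(ValueError, match="outside"):
        enrich(["zz"], collection(a=["g1"]), ["g1"])


@pytest.mark.parametrize("seed", range(6))
def test_enrich_matches_exhaustive_enumeration(seed):
    """p equals the exact fraction of same-size queries with >= overlap."""
    rng = np.random.default_rng(seed)
    u = int(rng.integers(6, 13))
    universe = [f"g{i}" for i in range(u)]
    set_genes = list(rng.choice(universe, size=int(rng.integers(2, u)), replace=False))
    q = int(rng.integers(1, u))
    query = list(rng.choice(universe, size=q, replace=False))
    (res,) = enrich(query, collection(s=set_genes), universe)
    observed = len(set(query) & set(set_genes))
    count = total = 0
    for draw in itertools.combinations(universe, q):
        total += 1
        if len(set(draw) & set(set_genes)) >= observed:
            count += 1
    assert res.p_value == pytest.approx(count / total, rel=1e-9)


def test_significant_sets_subsets_collection():
    universe = [f"g{i}" for i in range(12)]
    sets = collection(hit=universe[:4], miss=universe[8:])
    results = enrich(universe[:4], sets, universe)
    sig = significant_sets(results, sets)
    assert sig.names() == ["hit"]


# --- binary set features ----------------------------------------------------

def test_binary_features_membership_rule():
    """A patient mutated in any member gene gets feature value 1."""
    sets = collection(pathway=["TP53", "ATM"])
    feats = binary_set_features(
        [snp("p1", "TP53")], ["p1", "p2"], sets
    )
    assert feats.loc["p1", "pathway"] == 1
    assert feats.loc["p2", "pathway"] == 0
    assert set(np.unique(feats.to_numpy())) <= {0, 1}


def test_binary_features_unmutated_set_warns_constant_zero():
    sets = collection(ghost=["NOPE"])
    with pytest.warns(UserWarning, match="no mutated gene"):
        feats = binary_set_features([snp("p1", "TP53")], ["p1"], sets)
    assert (feats["ghost"] == 0).all()


def test_binary_features_column_count_and_order():
    sets = collection(a=["TP53"], b=["ATM"], c=["BRCA1"])
    feats = binary_set_features([snp("p1", "TP53")], ["p1", "p2"], sets)
    assert list(feats.columns) == ["a", "b", "c"]
    assert list(feats.index) == ["p1", "p2"]


# --- univariate gate --------------------------------------------------------

def test_gate_boundaries_strict():
    assert passes_univariate_gate(0.01, 1.30)
    assert not passes_univariate_gate(0.01, 1.221)  # boundary HR rejected
    assert not passes_univariate_gate(0.05, 1.30)  # boundary p rejected
    assert not passes_univariate_gate(0.20, 2.0)
    assert not passes_univariate_gate(0.01, 0.5)  # protective direction dropped


def test_filter_keeps_harmful_features_only():
    rng = np.random.default_rng(0)
    n = 300
    risky = rng.normal(size=n)
    protective = rng.normal(size=n)
    noise = rng.normal(size=n)
    hazard = 0.01 * np.exp(1.0 * risky - 1.0 * protective)
    times = rng.exponential(1 / hazard)
    surv = make_survival(times, np.ones(n, dtype=int))
    feats = pd.DataFrame(
        {"risky": risky, "protective": protective, "noise": noise},
        index=surv.sample_ids,
    )
    kept = filter_features_univariate(feats, surv)
    assert list(kept.columns) == ["risky"]


def test_filter_idempotent():
    rng = np.random.default_rng(1)
    n = 200
    x = rng.normal(size=n)
    times = rng.exponential(1 / (0.01 * np.exp(x)))
    surv = make_survival(times, np.ones(n, dtype=int))
    feats = pd.DataFrame({"x": x, "junk": rng.normal(size=n)}, index=surv.sample_ids)
    once = filter_features_univariate(feats, surv)
    twice = filter_features_univariate(once, surv)
    pd.testing.assert_frame_equal(once, twice)


# --- combined model ---------------------------------------------------------

def test_combined_empty_mutation_features_reduces_to_expression(small_cohort):
    expr_feats = small_cohort.expression.subset_genes(
        small_cohort.truth.risk_gene_ids
    ).frame.T
    empty = pd.DataFrame(index=expr_feats.index)
    ev_combined = combined_model(expr_feats, empty, small_cohort.survival, seed=3)
    from survsig.risk import cluster_risk_groups, evaluate_risk_model

    grouping = cluster_risk_groups(
        minmax_normalize(expr_feats), small_cohort.survival, seed=3
    )
    ev_expr = evaluate_risk_model(grouping, small_cohort.survival)
    assert ev_combined.c_index == pytest.approx(ev_expr.c_index)
    assert ev_combined.logrank_p == pytest.approx(ev_expr.logrank_p)


def test_combined_sample_mismatch_error(small_cohort):
    expr_feats = small_cohort.expression.subset_genes(
        small_cohort.truth.risk_gene_ids
    ).frame.T
    bad = pd.DataFrame(
        {"set1": 0}, index=["nobody"]
    )
    with pytest.raises(ValueError, match="mismatch"):
        combined_model(expr_feats, bad, small_cohort.survival)


def test_combined_with_planted_mutation_signal_not_worse():
    """Adding informative binary set features never costs much C-index."""
    hits = 0
    seeds = range(5)
    for seed in seeds:
        cohort = simulate_cohort(
            CohortSpec(
                n_samples=300, n_genes=60, n_risk_genes=10, n_diff_mut_genes=15,
                hazard_beta=1.0, seed=seed,
            )
        )
        expr_feats = cohort.expression.subset_genes(
            cohort.truth.risk_gene_ids
        ).frame.T
        planted = GeneSetCollection()
        for name in cohort.truth.planted_set_names:
            planted.add(
                name, "d", cohort.gene_sets.genes_of(name)
            )
        mut_feats = binary_set_features(
            cohort.mutations, cohort.expression.sample_ids, planted
        )
        ev_expr = combined_model(
            expr_feats, pd.DataFrame(index=expr_feats.index),
            cohort.survival, seed=0,
        )
        ev_comb = combined_model(expr_feats, mut_feats, cohort.survival, seed=0)
        if ev_comb.c_index >= ev_expr.c_index - 0.01:
            hits += 1
    assert hits >= 4
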