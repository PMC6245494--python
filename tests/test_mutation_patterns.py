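"""Per-group mutation rates, MRDS, SNV spectra and pairwise
mutual-exclusivity / co-occurrence statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from survsig.io_formats import MutationRecord
from survsig.mutation import (
    CO_OCCURRENCE,
    MUTUAL_EXCLUSIVITY,
    SNV_TYPES,
    mrds,
    mutation_rates_by_group,
    pairwise_patterns,
    pattern_from_counts,
    snv_spectrum,
    top_k_by_mrds,
)
from survsig.risk import HIGH, LOW, RiskGrouping
from survsig.synthetic import CohortSpec, simulate_cohort


def snp(sample, gene, ref="C", alt="T"):
    return MutationRecord(sample, gene, "SNP", ref, alt)


def grouping_of(high_ids, low_ids):
    labels = pd.Series(
        [HIGH] * len(high_ids) + [LOW] * len(low_ids), index=high_ids + low_ids
    )
    return RiskGrouping(labels)


@pytest.fixture
def toy_grouping():
    return grouping_of([f"h{i}" for i in range(4)], [f"l{i}" for i in range(10)])


def test_rates_counting(toy_grouping):
    muts = [snp("h0", "TP53"), snp("h1", "TP53"), snp("l0", "TP53")]
    rates = mutation_rates_by_group(muts, toy_grouping)
    assert rates.loc["TP53", "r_high"] == 0.5
    assert rates.loc["TP53", "r_low"] == 0.1
    assert rates.loc["TP53", "n_high"] == 4 and rates.loc["TP53", "n_low"] == 10


def test_rates_sample_counted_once_per_gene(toy_grouping):
    muts = [snp("h0", "TP53", "C", "T"), snp("h0", "TP53", "A", "G")]
    rates = mutation_rates_by_group(muts, toy_grouping)
    assert rates.loc["TP53", "r_high"] == 0.25


def test_rates_unknown_samples_dropped_with_warning(toy_grouping):
    muts = [snp("h0", "TP53"), snp("zz", "TP53")]
    with pytest.warns(UserWarning, match="dropping"):
        rates = mutation_rates_by_group(muts, toy_grouping)
    assert rates.loc["TP53", "r_high"] == 0.25


def test_mrds_worked_value():
    """TP53 group rates 0.634 / 0.208 give MRDS ~ 4.667."""
    assert mrds(0.634, 0.208) == pytest.approx(4.667, abs=1e-3)


def test_mrds_identity_and_sentinels():
    assert mrds(0.3, 0.3) == pytest.approx(1.0)
    assert mrds(0.3, 0.0) == math.inf
    assert math.isnan(mrds(0.0, 0.0))
    with pytest.raises(ValueError):
        mrds(1.2, 0.1)


def test_mrds_reciprocal_symmetry():
    rng = np.random.default_rng(1)
    for _ in range(20):
        a, b = rng.uniform(0.01, 1.0, size=2)
        assert mrds(a, b) * mrds(b, a) == pytest.approx(1.0)


def test_top_k_ordering_and_ties():
    rates = pd.DataFrame(
        {
            "r_high": [0.5, 0.2, 0.1, 0.2],
            "r_low": [0.1, 0.1, 0.1, 0.1],
            "n_high": 10,
            "n_low": 10,
        },
        index=["gB", "gC", "gD", "gA"],
    )
    top = top_k_by_mrds(rates, k=2)
    assert top[0] == "gB"
    assert top[1] == "gA"  # tie with gC broken lexicographically
    with pytest.warns(UserWarning, match="only"):
        assert len(top_k_by_mrds(rates, k=99)) == 4


def test_top_k_excludes_undefined_and_ranks_inf_first():
    rates = pd.DataFrame(
        {
            "r_high": [0.2, 0.0, 0.3],
            "r_low": [0.0, 0.0, 0.1],
            "n_high": 10,
            "n_low": 10,
        },
        index=["gInf", "gNan", "gFin"],
    )
    with pytest.warns(UserWarning):
        top = top_k_by_mrds(rates, k=3)
    assert top == ["gInf", "gFin"]


def test_spectrum_per_sample_fractions(toy_grouping):
    muts = [
        snp("h0", "A1", "C", "G"),
        snp("h0", "A2", "C", "G"),
        snp("h0", "A3", "A", "T"),
        MutationRecord("h0", "A4", "DEL", "ACT", "-"),  # excluded (not SNP)
    ]
    with pytest.warns(UserWarning):
        fractions, _ = snv_spectrum(muts, toy_grouping)
    assert fractions.loc["h0", "C>G"] == pytest.approx(2 / 3)
    assert fractions.loc["h0", "A>T"] == pytest.approx(1 / 3)
    assert fractions.loc["h0"].sum() == pytest.approx(1.0)


def test_spectrum_identical_groups_p_one():
    g = grouping_of(["h0", "h1"], ["l0", "l1"])
    muts = [snp(s, "A1", "C", "G") for s in ["h0", "h1", "l0", "l1"]]
    fractions, tests = snv_spectrum(muts, g)
    assert tests.loc["C>G", "p_value"] == pytest.approx(1.0)
    assert (fractions.sum(axis=1) == 1.0).all()


def test_spectrum_small_group_skips_tests():
    g = grouping_of(["h0"], ["l0", "l1"])
    muts = [snp("h0", "A1"), snp("l0", "A1"), snp("l1", "A1")]
    with pytest.warns(UserWarning, match="skipped"):
        _, tests = snv_spectrum(muts, g)
    assert tests["p_value"].isna().all()


def test_spectrum_detects_planted_cg_shift():
    """C>G shift of 0.05 at n=400 is detected in most replicates."""
    hits = 0
    seeds = range(4)
    for seed in seeds:
        cohort = simulate_cohort(
            CohortSpec(n_samples=400, snv_cg_shift=0.05, seed=seed)
        )
        grouping = RiskGrouping(cohort.truth.true_group.copy())
        with np.errstate(all="ignore"):
            _, tests = snv_spectrum(cohort.mutations, grouping)
        if tests.loc["C>G", "p_value"] < 0.05:
            hits += 1
    assert hits >= 0.8 * len(seeds)


def test_pairwise_worked_log_odds():
    """TP53/CDH1 printed counts (338,125,9) with 1066 samples: ln OR -2.067."""
    p = pattern_from_counts("TP53", "CDH1", 338, 125, 9, 1066)
    assert p.neither == 594
    assert p.log_odds_ratio == pytest.approx(-2.067, abs=5e-4)
    p2 = pattern_from_counts("TTN", "MUC16", 146, 68, 41, 1066)
    assert p2.log_odds_ratio == pytest.approx(1.209, abs=5e-4)


def test_pairwise_symmetry_in_gene_roles():
    a = pattern_from_counts("A", "B", 30, 12, 5, 200)
    b = pattern_from_counts("B", "A", 12, 30, 5, 200)
    assert a.log_odds_ratio == pytest.approx(b.log_odds_ratio)
    assert a.p_value == pytest.approx(b.p_value)


def test_pairwise_zero_both_is_negative_infinity():
    p = pattern_from_counts("A", "B", 10, 10, 0, 100)
    assert p.log_odds_ratio == -math.inf


def test_pairwise_patterns_from_records_and_tendency():
    high = [f"s{i}" for i in range(30)]
    # geneA and geneB co-occur in the same 10 samples; geneC hits 10 others
    muts = (
        [snp(s, "geneA") for s in high[:10]]
        + [snp(s, "geneB") for s in high[:10]]
        + [snp(s, "geneC") for s in high[10:20]]
    )
    pats = pairwise_patterns(muts, ["geneA", "geneB", "geneC"], total_samples=30)
    byname = {(p.gene_a, p.gene_b): p for p in pats}
    ab = byname[("geneA", "geneB")]
    assert ab.both == 10 and ab.a_not_b == 0 and ab.neither == 20
    assert ab.log_odds_ratio == math.inf
    assert ab.tendency == CO_OCCURRENCE
    ac = byname[("geneA", "geneC")]
    assert ac.both == 0 and ac.log_odds_ratio == -math.inf
    assert ac.tendency == MUTUAL_EXCLUSIVITY


def test_pairwise_skips_unmutated_gene():
    muts = [snp("s1", "geneA")]
    with pytest.warns(UserWarning, match="zero margin"):
        pats = pairwise_patterns(muts, ["geneA", "ghost"], total_samples=10)
    assert pats == []


def test_pairwise_counts_partition_total():
    rng = np.random.default_rng(2)
    samples = [f"s{i}" for i in range(50)]
    muts = [
        snp(s, g)
        for g in ("g1", "g2")
        for s in rng.choice(samples, size=20, replace=False)
    ]
    (p,) = pairwise_patterns(muts, ["g1", "g2"], total_samples=50)
    assert p.a_not_b + p.b_not_a + p.both + p.neither == 50
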