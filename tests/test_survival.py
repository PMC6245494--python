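"""Cox PH, concordance, Kaplan-Meier, log-rank: worked examples, oracle
cross-checks (independent Efron partial likelihood + lifelines), and
invariant properties."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import stats

from survsig.io_formats import SurvivalTable
from survsig.survival import (
    RankDeficiencyError,
    concordance_index,
    cox_multivariate,
    cox_univariate,
    km_estimate,
    logrank_test,
    pearson_coef,
)

from conftest import make_survival, random_survival


# --- independent oracle: naive Efron partial log-likelihood -----------------

def efron_loglik(beta, x, times, events):
    """Direct textbook evaluation, independent of the package internals."""
    beta = np.atleast_1d(beta)
    X = np.atleast_2d(x).T if np.ndim(x) == 1 else x
    eta = X @ beta
    ll = 0.0
    for t in np.unique(times[events == 1]):
        D = np.flatnonzero((times == t) & (events == 1))
        R = np.flatnonzero(times >= t)
        d = len(D)
        s_r = np.exp(eta[R]).sum()
        s_d = np.exp(eta[D]).sum()
        ll += eta[D].sum()
        for l in range(d):
            ll -= np.log(s_r - (l / d) * s_d)
    return ll


def grid_max(x, times, events, lo=-5, hi=5):
    """Two-stage brute-force grid maximization of the Efron likelihood."""
    for _ in range(2):
        grid = np.linspace(lo, hi, 2001)
        vals = [efron_loglik(b, x, times, events) for b in grid]
        best = grid[int(np.argmax(vals))]
        span = (hi - lo) / 2000
        lo, hi = best - 2 * span, best + 2 * span
    return best


# --- univariate Cox ---------------------------------------------------------

def test_cox_closed_form_example(four_events):
    """Times 1..4, x=[1,0,1,0]: the score equation reduces to u^2-u-4=0."""
    res = cox_univariate(np.array([1.0, 0.0, 1.0, 0.0]), four_events)
    expected = np.log((1 + np.sqrt(17)) / 2)
    assert res.coef == pytest.approx(expected, abs=1e-6)
    assert res.hazard_ratio == pytest.approx(np.exp(expected), abs=1e-5)
    assert res.converged


def test_cox_constant_feature_convention(four_events):
    with pytest.warns(UserWarning, match="constant"):
        res = cox_univariate(np.ones(4), four_events)
    assert res.coef == 0.0 and res.hazard_ratio == 1.0 and res.p_value == 1.0


def test_cox_negated_feature_flips_sign(four_events):
    x = np.array([0.5, -1.0, 2.0, 0.0])
    a = cox_univariate(x, four_events)
    b = cox_univariate(-x, four_events)
    assert a.coef == pytest.approx(-b.coef, abs=1e-9)


def test_cox_zero_events_error():
    surv = make_survival([1, 2, 3], [0, 0, 0])
    with pytest.raises(ValueError, match="zero events"):
        cox_univariate(np.array([1.0, 2.0, 3.0]), surv)


@pytest.mark.parametrize("seed", range(8))
def test_cox_matches_grid_search_oracle(seed):
    """MLE agrees with brute-force grid maximization on tie-prone data."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 13))
    surv = random_survival(rng, n, max_time=6)
    x = rng.normal(size=n)
    res = cox_univariate(x, surv)
    if not res.converged:
        pytest.skip("separation draw")
    oracle = grid_max(x, surv.times, surv.events)
    assert res.coef == pytest.approx(oracle, abs=1e-4)


@pytest.mark.parametrize("seed", range(5))
def test_cox_matches_lifelines(seed):
    """Coefficient and Wald p agree with lifelines' Efron implementation."""
    rng = np.random.default_rng(100 + seed)
    n = 40
    surv = random_survival(rng, n, max_time=12)
    x = rng.normal(size=n)
    res = cox_univariate(x, surv)
    cph = CoxPHFitter().fit(
        pd.DataFrame({"t": surv.times, "e": surv.events, "x": x}), "t", "e"
    )
    assert res.coef == pytest.approx(cph.params_["x"], abs=1e-4)
    assert res.p_value == pytest.approx(cph.summary["p"]["x"], abs=1e-3)


def test_cox_separation_reported_not_converged():
    # feature perfectly orders an all-event dataset: monotone likelihood
    surv = make_survival([1, 2, 3, 4, 5, 6], [1] * 6)
    x = np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
    with pytest.warns(UserWarning, match="converge"):
        res = cox_univariate(x, surv)
    assert not res.converged
    assert res.coef > 0  # sign of the divergence is preserved


# --- multivariate Cox -------------------------------------------------------

def test_multivariate_single_column_reduces_to_univariate(four_events):
    x = np.array([1.0, 0.0, 1.0, 0.0])
    uni = cox_univariate(x, four_events)
    multi = cox_multivariate(pd.DataFrame({"x": x}), four_events)
    assert len(multi) == 1
    assert multi[0].coef == pytest.approx(uni.coef, abs=1e-8)
    assert multi[0].p_value == pytest.approx(uni.p_value, abs=1e-8)


def test_multivariate_duplicated_column_rank_error(four_events):
    x = np.array([1.0, 0.0, 1.0, 0.0])
    frame = pd.DataFrame({"a": x, "b": x})
    with pytest.raises(RankDeficiencyError) as exc:
        cox_multivariate(frame, four_events)
    assert "b" in exc.value.columns or "a" in exc.value.columns


def test_multivariate_matches_lifelines_joint_fit():
    rng = np.random.default_rng(7)
    n = 60
    surv = random_survival(rng, n, max_time=15)
    X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
    mine = cox_multivariate(X, surv)
    cph = CoxPHFitter().fit(
        pd.concat(
            [X, pd.DataFrame({"t": surv.times, "e": surv.events})], axis=1
        ),
        "t",
        "e",
    )
    for res in mine:
        assert res.coef == pytest.approx(cph.params_[res.feature_name], abs=1e-4)


def test_multivariate_recovers_planted_signs():
    """Two independent planted effects recover their signs on PH data."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(200 + seed)
        n = 150
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        hazard = 0.01 * np.exp(0.8 * x1 - 0.8 * x2)
        t = rng.exponential(1 / hazard)
        surv = make_survival(t, np.ones(n, dtype=int))
        res = cox_multivariate(pd.DataFrame({"x1": x1, "x2": x2}), surv)
        if res[0].coef > 0 and res[1].coef < 0:
            hits += 1
    assert hits >= 9


# --- concordance index ------------------------------------------------------

def test_concordance_worked_examples(four_events):
    perfect = make_survival([2, 5, 4], [1, 1, 1])
    assert concordance_index([0.9, 0.2, 0.6], perfect) == 1.0
    partial = make_survival([2, 4, 5], [1, 1, 1])
    assert concordance_index([0.9, 0.2, 0.6], partial) == pytest.approx(2 / 3)
    # two tied-score comparable pairs contribute 0.5 each
    assert concordance_index([3.0, 0.0, 3.0, 0.0], four_events) == pytest.approx(4 / 6)


def test_concordance_no_comparable_pairs_warns_half():
    surv = make_survival([1, 2, 3], [0, 0, 1])  # only the largest time has an event
    with pytest.warns(UserWarning, match="no comparable pairs"):
        assert concordance_index([1.0, 2.0, 3.0], surv) == 0.5


def test_concordance_complement_symmetry():
    rng = np.random.default_rng(3)
    surv = random_survival(rng, 25, max_time=50)  # continuous-ish times
    scores = rng.normal(size=25)
    c = concordance_index(scores, surv)
    assert c + concordance_index(-scores, surv) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(10))
def test_concordance_matches_pair_enumeration(seed):
    rng = np.random.default_rng(400 + seed)
    n = int(rng.integers(5, 31))
    surv = random_survival(rng, n, max_time=8)
    scores = rng.choice([0.0, 0.25, 0.5, 1.0], size=n)  # force score ties
    t, e = surv.times, surv.events
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if t[i] < t[j] and e[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    if den == 0:
        pytest.skip("degenerate draw")
    assert concordance_index(scores, surv) == pytest.approx(num / den)


# --- Kaplan-Meier -----------------------------------------------------------

def test_km_worked_example():
    surv = make_survival([1, 2, 3], [1, 0, 1])
    curve = km_estimate(surv)
    assert curve.event_times.tolist() == [0.0, 1.0, 3.0]
    assert curve.survival_probabilities == pytest.approx([1.0, 2 / 3, 0.0])
    assert curve.n_at_risk.tolist() == [3.0, 3.0, 1.0]


def test_km_no_events_flat_at_one():
    surv = make_survival([5, 7, 9], [0, 0, 0])
    curve = km_estimate(surv)
    assert np.all(curve.survival_probabilities == 1.0)


def test_km_no_censoring_equals_empirical_survival():
    rng = np.random.default_rng(5)
    times = rng.permutation(np.arange(1.0, 11.0))
    surv = make_survival(times, np.ones(10, dtype=int))
    curve = km_estimate(surv)
    # at each distinct event time, S(t) = fraction with time > t
    for t, s in zip(curve.event_times[1:], curve.survival_probabilities[1:]):
        assert s == pytest.approx(np.mean(times > t))


def test_km_probabilities_non_increasing(small_cohort):
    curve = km_estimate(small_cohort.survival)
    assert np.all(np.diff(curve.survival_probabilities) <= 1e-12)
    assert curve.survival_probabilities[0] == 1.0


# --- log-rank ---------------------------------------------------------------

def test_logrank_identical_groups_null():
    surv = make_survival([1, 2, 1, 2], [1, 1, 1, 1])
    stat, p = logrank_test(np.array(["A", "A", "B", "B"]), surv)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_worked_example():
    surv = make_survival([1, 1, 2, 2], [1, 1, 1, 1])
    stat, p = logrank_test(np.array(["A", "A", "B", "B"]), surv)
    assert stat == pytest.approx(3.0, abs=1e-9)
    assert p == pytest.approx(0.0833, abs=5e-4)


def test_logrank_label_swap_invariance():
    rng = np.random.default_rng(9)
    surv = random_survival(rng, 30)
    labels = rng.choice(["A", "B"], size=30)
    if len(set(labels)) < 2:
        labels[0] = "A" if labels[0] == "B" else "B"
    s1, p1 = logrank_test(labels, surv)
    swapped = np.where(labels == "A", "B", "A")
    s2, p2 = logrank_test(swapped, surv)
    assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)


def test_logrank_empty_group_error():
    surv = make_survival([1, 2, 3], [1, 1, 1])
    with pytest.raises(ValueError, match="2"):
        logrank_test(np.array(["A", "A", "A"]), surv)


def test_logrank_null_p_values_uniform():
    """Under no group effect the p-values are Uniform(0,1) (KS check)."""
    rng = np.random.default_rng(12345)
    pvals = []
    for _ in range(1000):
        n = 24
        times = rng.exponential(10.0, size=n)
        events = (rng.random(n) > 0.25).astype(int)
        if events.sum() == 0:
            continue
        surv = make_survival(times, events)
        labels = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        pvals.append(logrank_test(labels, surv)[1])
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


# --- Pearson diagnostic -----------------------------------------------------

def test_pearson_examples():
    x = np.array([1.0, 2.0, 3.0])
    assert pearson_coef(x, 2 * x + 1) == pytest.approx(1.0)
    assert pearson_coef(x, -x) == pytest.approx(-1.0)
    assert pearson_coef(x, np.array([1.0, 3.0, 2.0])) == pytest.approx(0.5)


def test_pearson_constant_vector_error():
    with pytest.raises(ValueError, match="constant"):
        pearson_coef(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))
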