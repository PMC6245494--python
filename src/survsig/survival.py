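"""Core survival statistics: Cox proportional hazards (Efron ties),
Harrell's concordance index, Kaplan-Meier curves and the two-group
log-rank test.

The Cox partial likelihood is maximized in-package by Newton-Raphson with
Efron's tie correction (the default of the R ``survival`` package), with a
tight tolerance on the score so the estimate can be compared against
closed-form and grid-search oracles.  Kaplan-Meier and log-rank are thin
wrappers over lifelines.

The concordance index follows a fixed convention: a pair of samples is
comparable iff the member with the smaller observed time had the event;
tied risk scores in a comparable pair contribute 0.5; with no comparable
pairs the index is 0.5 by convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import linalg, stats

from .io_formats import SurvivalTable

__all__ = [
    "CoxResult",
    "KMCurve",
    "cox_univariate",
    "cox_multivariate",
    "concordance_index",
    "km_estimate",
    "logrank_test",
    "pearson_coef",
]


@dataclass
class CoxResult:
    """One Cox coefficient: log hazard ratio, HR = exp(coef), Wald p."""

    feature_name: str
    coef: float
    hazard_ratio: float
    p_value: float
    se: float
    converged: bool = True


@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated at the event times.

    Arrays start at t=0 with S=1 and are aligned; probabilities are
    non-increasing.
    """

    event_times: np.ndarray
    survival_probabilities: np.ndarray
    n_at_risk: np.ndarray


class RankDeficiencyError(ValueError):
    """Feature matrix contains linearly dependent columns."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"linearly dependent feature columns: {columns}")


def _efron_negloglik(
    beta: np.ndarray, X: np.ndarray, times: np.ndarray, events: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Negative Efron partial log-likelihood with gradient and Hessian.

    Subjects are processed by descending time so the risk-set sums are
    cumulative.
    """
    n, p = X.shape
    order = np.argsort(-times, kind="stable")
    Xs, ts, es = X[order], times[order], events[order]
    eta = Xs @ beta
    # guard against overflow in exp for diverging beta
    w = np.exp(np.clip(eta, -500, 500))
    neg = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    s_r = 0.0
    z_r = np.zeros(p)
    h_r = np.zeros((p, p))
    i = 0
    while i < n:
        t = ts[i]
        j = i
        while j < n and ts[j] == t:
            j += 1
        # add the whole tied-time block to the risk set
        for k in range(i, j):
            s_r += w[k]
            z_r += w[k] * Xs[k]
            h_r += w[k] * np.outer(Xs[k], Xs[k])
        death_idx = [k for k in range(i, j) if es[k] == 1]
        d = len(death_idx)
        if d:
            s_d = float(np.sum(w[death_idx]))
            z_d = (w[death_idx, None] * Xs[death_idx]).sum(axis=0)
            h_d = np.einsum("k,ki,kj->ij", w[death_idx], Xs[death_idx], Xs[death_idx])
            neg -= float(np.sum(eta[death_idx]))
            for l in range(d):
                frac = l / d
                phi = s_r - frac * s_d
                z_l = z_r - frac * z_d
                h_l = h_r - frac * h_d
                neg += math.log(phi)
                grad += z_l / phi
                hess += h_l / phi - np.outer(z_l, z_l) / (phi * phi)
            grad -= Xs[death_idx].sum(axis=0)
        i = j
    return neg, grad, hess


def _fit_cox(
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    score_tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson on the Efron partial likelihood.

    Returns (beta, covariance, converged).  Monotone likelihood (perfect
    separation) shows up as a diverging coefficient; it is reported as
    non-converged, keeping the sign of the divergence.
    """
    n, p = X.shape
    beta = np.zeros(p)
    neg, grad, hess = _efron_negloglik(beta, X, times, events)
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < score_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # step-halving to keep the likelihood monotone
        scale = 1.0
        for _ in range(30):
            cand = beta - scale * step
            neg_c, grad_c, hess_c = _efron_negloglik(cand, X, times, events)
            if neg_c <= neg + 1e-12:
                beta, neg, grad, hess = cand, neg_c, grad_c, hess_c
                break
            scale /= 2.0
        else:
            break
        if np.max(np.abs(beta)) > 30:
            # monotone likelihood: coefficient runs away
            break
    else:
        _, grad, hess = _efron_negloglik(beta, X, times, events)
        converged = bool(np.max(np.abs(grad)) < score_tol)
    if not converged and np.max(np.abs(grad)) < score_tol:
        converged = True
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    # monotone likelihood: the score can vanish while the coefficient runs
    # away and the likelihood flattens (huge variance) -- flag it
    if converged:
        for j in range(p):
            se = np.sqrt(cov[j, j]) if np.isfinite(cov[j, j]) else np.inf
            if abs(beta[j]) > 10 and se > abs(beta[j]):
                converged = False
                break
    return beta, cov, converged


def _wald_p(coef: float, se: float) -> float:
    if not np.isfinite(se) or se <= 0:
        return float("nan")
    z = coef / se
    return float(2.0 * stats.norm.sf(abs(z)))


def cox_univariate(
    feature: np.ndarray | pd.Series,
    survival: SurvivalTable,
    name: str = "feature",
) -> CoxResult:
    """Univariate Cox PH fit of one feature against survival.

    A constant feature carries no information: by convention coef=0, HR=1,
    p=1 with a warning.  Zero events is an error.
    """
    x = np.asarray(feature, dtype=float)
    if x.shape[0] != survival.n:
        raise ValueError(
            f"feature length {x.shape[0]} != number of samples {survival.n}"
        )
    if survival.events.sum() == 0:
        raise ValueError("cannot fit Cox model with zero events")
    if np.ptp(x) == 0:
        warnings.warn(f"feature {name!r} is constant; coef=0, p=1 by convention")
        return CoxResult(name, 0.0, 1.0, 1.0, float("nan"))
    beta, cov, converged = _fit_cox(x[:, None], survival.times, survival.events)
    coef = float(beta[0])
    se = float(np.sqrt(cov[0, 0])) if np.isfinite(cov[0, 0]) else float("nan")
    if not converged:
        sign = "+" if coef > 0 else "-"
        warnings.warn(
            f"Cox fit for {name!r} did not converge "
            f"(possible monotone likelihood, sign {sign})"
        )
    return CoxResult(name, coef, float(np.exp(coef)), _wald_p(coef, se), se, converged)


def cox_multivariate(
    features: pd.DataFrame, survival: SurvivalTable
) -> list[CoxResult]:
    """Joint Cox PH fit over all feature columns (samples in rows).

    Exactly collinear columns are detected up front via pivoted QR and
    reported by name.
    """
    if features.shape[0] != survival.n:
        raise ValueError("feature table and survival table sample counts differ")
    X = features.to_numpy(dtype=float)
    if survival.events.sum() == 0:
        raise ValueError("cannot fit Cox model with zero events")
    Xc = X - X.mean(axis=0)
    _, R, piv = linalg.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(Xc.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        dependent = [features.columns[i] for i in sorted(piv[rank:])]
        raise RankDeficiencyError(dependent)
    beta, cov, converged = _fit_cox(X, survival.times, survival.events)
    results = []
    for i, col in enumerate(features.columns):
        se = float(np.sqrt(cov[i, i])) if np.isfinite(cov[i, i]) else float("nan")
        coef = float(beta[i])
        results.append(
            CoxResult(str(col), coef, float(np.exp(coef)), _wald_p(coef, se), se, converged)
        )
    if not converged:
        warnings.warn("multivariate Cox fit did not converge")
    return results


def concordance_index(
    risk_scores: np.ndarray | pd.Series, survival: SurvivalTable
) -> float:
    """Harrell's C over comparable pairs (see module docstring for ties)."""
    s = np.asarray(risk_scores, dtype=float)
    if s.shape[0] != survival.n:
        raise ValueError("risk score length != number of samples")
    t, e = survival.times, survival.events
    # comparable (i,j): t_i < t_j and event_i == 1
    ti = t[:, None]
    comparable = (ti < t[None, :]) & (e[:, None] == 1)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        warnings.warn("no comparable pairs; concordance index 0.5 by convention")
        return 0.5
    si = s[:, None]
    concordant = comparable & (si > s[None, :])
    tied = comparable & (si == s[None, :])
    return float((concordant.sum() + 0.5 * tied.sum()) / n_pairs)


def km_estimate(survival: SurvivalTable) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    if survival.n == 0:
        raise ValueError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(survival.times, survival.events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = np.concatenate([[0.0], event_rows.index.to_numpy(dtype=float)])
    sf = kmf.survival_function_["KM_estimate"]
    probs = np.concatenate([[1.0], sf.loc[event_rows.index].to_numpy(dtype=float)])
    at_risk = np.concatenate(
        [[survival.n], event_rows["at_risk"].to_numpy(dtype=float)]
    )
    return KMCurve(times, probs, at_risk)


def logrank_test(
    labels: pd.Series | np.ndarray, survival: SurvivalTable
) -> tuple[float, float]:
    """Two-group log-rank test; ``labels`` aligned with the survival rows."""
    lab = np.asarray(labels)
    if lab.shape[0] != survival.n:
        raise ValueError("label length != number of samples")
    groups = pd.unique(lab)
    if len(groups) != 2:
        raise ValueError(f"log-rank test needs exactly 2 non-empty groups, got {len(groups)}")
    mask = lab == groups[0]
    res = _ll_logrank(
        survival.times[mask],
        survival.times[~mask],
        survival.events[mask],
        survival.events[~mask],
    )
    return float(res.test_statistic), float(res.p_value)


def pearson_coef(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation (diagnostic helper)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need equal-length vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])
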