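"""Risk stratification: per-feature min-max normalization, k-means (k=2)
clustering of samples, high/low labeling by event fraction, and evaluation
of the resulting two-group survival model (Cox on the group indicator,
concordance index, Kaplan-Meier curves, log-rank test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io_formats import SurvivalTable
from .survival import (
    KMCurve,
    concordance_index,
    cox_univariate,
    km_estimate,
    logrank_test,
)

HIGH, LOW = "high", "low"


@dataclass
class RiskGrouping:
    """Per-sample high/low risk labels plus the statistics that oriented them."""

    labels: pd.Series  # index = sample_id, values in {"high", "low"}
    labeling_statistic: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = set(self.labels.unique())
        if vals != {HIGH, LOW}:
            raise ValueError(f"grouping must contain both labels, got {vals}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def indicator(self) -> np.ndarray:
        """1 for high-risk, 0 for low-risk, in label order."""
        return (self.labels == HIGH).to_numpy(dtype=float)

    def swapped(self) -> "RiskGrouping":
        flipped = self.labels.map({HIGH: LOW, LOW: HIGH})
        return RiskGrouping(flipped, dict(self.labeling_statistic))


@dataclass
class RiskModelEvaluation:
    cox_p: float
    hazard_ratio: float
    c_index: float
    km_high: KMCurve
    km_low: KMCurve
    logrank_statistic: float
    logrank_p: float


def minmax_normalize(features: pd.DataFrame) -> pd.DataFrame:
    """Map each feature column to [0,1] via (g - min) / (max - min).

    A constant column is mapped to all zeros (with a warning) rather than
    dropped, so feature indices stay stable for GA chromosomes.
    """
    if features.shape[0] < 1:
        raise ValueError("empty feature table")
    mn = features.min(axis=0)
    mx = features.max(axis=0)
    span = mx - mn
    constant = span == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) normalized to all-zeros"
        )
    safe_span = span.replace(0, 1.0)
    out = (features - mn) / safe_span
    out.loc[:, constant] = 0.0
    return out


def cluster_risk_groups(
    features: pd.DataFrame,
    survival: SurvivalTable,
    seed: int = 0,
    n_init: int = 10,
) -> RiskGrouping:
    """k-means (k=2) over samples in normalized feature space.

    The cluster with the higher event fraction is labeled high risk; on a
    tie the cluster with the lower mean observed time is high.
    """
    if features.shape[0] < 4:
        raise ValueError("need at least 4 samples to cluster")
    X = features.to_numpy(dtype=float)
    if np.all(X == X[0]):
        raise ValueError("all samples identical; clustering undefined")
    if list(features.index) != survival.sample_ids:
        raise ValueError("feature table rows must align with the survival table")
    km = KMeans(n_clusters=2, init="k-means++", n_init=n_init, random_state=seed)
    assign = km.fit_predict(X)
    events = survival.events
    times = survival.times
    stats = {}
    for c in (0, 1):
        m = assign == c
        stats[c] = {
            "n": int(m.sum()),
            "event_fraction": float(events[m].mean()),
            "mean_time": float(times[m].mean()),
        }
    ef0, ef1 = stats[0]["event_fraction"], stats[1]["event_fraction"]
    if ef0 != ef1:
        high_cluster = 0 if ef0 > ef1 else 1
    else:  # tie: shorter mean observed time marks the high-risk cluster
        high_cluster = 0 if stats[0]["mean_time"] <= stats[1]["mean_time"] else 1
    labels = pd.Series(
        np.where(assign == high_cluster, HIGH, LOW), index=features.index
    )
    statistic = {
        HIGH: stats[high_cluster],
        LOW: stats[1 - high_cluster],
    }
    return RiskGrouping(labels, statistic)


def evaluate_risk_model(
    grouping: RiskGrouping, survival: SurvivalTable
) -> RiskModelEvaluation:
    """Fit Cox PH on the binary high-risk indicator and evaluate it.

    The concordance index is computed on the high/low indicator itself
    (identical to the fitted Cox linear predictor whenever the fitted
    coefficient is positive, i.e. whenever the event-fraction labeling put
    the truly riskier cluster on "high"); Kaplan-Meier curves are
    estimated per group.
    """
    labels = grouping.labels.loc[survival.sample_ids]
    indicator = (labels == HIGH).to_numpy(dtype=float)
    cox = cox_univariate(indicator, survival, name="high_risk")
    c_index = concordance_index(indicator, survival)
    high_ids = [s for s, l in labels.items() if l == HIGH]
    low_ids = [s for s, l in labels.items() if l == LOW]
    km_high = km_estimate(survival.subset(high_ids))
    km_low = km_estimate(survival.subset(low_ids))
    lr_stat, lr_p = logrank_test(labels.to_numpy(), survival)
    return RiskModelEvaluation(
        cox_p=cox.p_value,
        hazard_ratio=cox.hazard_ratio,
        c_index=c_index,
        km_high=km_high,
        km_low=km_low,
        logrank_statistic=lr_stat,
        logrank_p=lr_p,
    )


def group_label_concordance(grouping: RiskGrouping, survival: SurvivalTable) -> float:
    """C-index of the raw high/low indicator (fast path used by the GA)."""
    labels = grouping.labels.loc[survival.sample_ids]
    return concordance_index((labels == HIGH).to_numpy(dtype=float), survival)
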