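"""Differential-expression screen between tumor and normal samples.

A deliberately simple screen: per-gene Welch t-test on log2(x+1) values
with Benjamini-Hochberg adjustment, gated at adjusted p < 0.01 and
|log2 fold change| > 2.  Users with a full negative-binomial DE table
(e.g. from edgeR) can feed it in via the pipeline's external-table entry
point; the gate semantics (effect size + adjusted p) are identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

DEFAULT_ALPHA = 0.01
DEFAULT_LFC = 2.0


@dataclass
class DEResult:
    gene: str
    log_fc: float  # mean log2(tumor+1) - mean log2(normal+1)
    p_value: float
    p_adjusted: float
    significant: bool


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    alpha: float = DEFAULT_ALPHA,
    lfc_threshold: float = DEFAULT_LFC,
) -> list[DEResult]:
    """Welch t-test per gene on log2(x+1), BH-adjusted, thresholded.

    A gene is significant iff adjusted p < ``alpha`` and |log2 FC| >
    ``lfc_threshold`` (strict inequalities).  A gene with zero variance on
    both sides gets p = 1 by convention with a warning.
    """
    if tumor.gene_ids != normal.gene_ids:
        raise ValueError("tumor and normal matrices must share the same gene list")
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("need at least 2 samples per side")
    t_log = tumor.log2().values
    n_log = normal.log2().values
    log_fc = t_log.mean(axis=1) - n_log.mean(axis=1)
    p_values = np.ones(len(log_fc))
    zero_var = 0
    for i in range(len(log_fc)):
        a, b = t_log[i], n_log[i]
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            zero_var += 1
            p_values[i] = 1.0
            continue
        p_values[i] = stats.ttest_ind(a, b, equal_var=False)[1]
    if zero_var:
        warnings.warn(f"{zero_var} genes had zero variance on both sides; p=1")
    p_adj = bh_adjust(p_values)
    return [
        DEResult(
            gene=g,
            log_fc=float(lfc),
            p_value=float(p),
            p_adjusted=float(pa),
            significant=bool(pa < alpha and abs(lfc) > lfc_threshold),
        )
        for g, lfc, p, pa in zip(tumor.gene_ids, log_fc, p_values, p_adj)
    ]


def de_results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "log_fc": r.log_fc,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def significant_genes(results: list[DEResult]) -> list[str]:
    return [r.gene for r in results if r.significant]
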