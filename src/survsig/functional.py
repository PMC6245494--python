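"""Gene-set enrichment of differentially mutated genes and conversion of
significant sets into binary patient features.

Over-representation is tested with the hypergeometric upper tail
P[X >= overlap] against a user-supplied GMT collection, BH-adjusted across
sets, gated at p < 0.05.  Each significant set then becomes one 0/1
patient feature: 1 iff the patient carries a mutation in at least one of
the set's genes.  The binary features are filtered by univariate Cox
(p < 0.05 and HR > 1.221, strict) exactly like expression features, and a
combined expression + mutation risk model is evaluated end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io_formats import GeneSetCollection, MutationRecord, SurvivalTable
from .mutation import samples_with_mutation
from .risk import RiskModelEvaluation, cluster_risk_groups, evaluate_risk_model, minmax_normalize
from .survival import cox_univariate

ENRICH_ALPHA = 0.05
COX_ALPHA = 0.05
HR_THRESHOLD = 1.221


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    p_adjusted: float = float("nan")
    significant: bool = False


def enrich(
    query_genes: Sequence[str],
    sets: GeneSetCollection,
    universe: Sequence[str],
    alpha: float = ENRICH_ALPHA,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of the query in each gene set.

    Sets are intersected with the universe; the query must be a subset of
    the universe.  p = P[X >= overlap] for X ~ Hypergeom(universe, set,
    query); BH adjustment across sets; significance gate p < alpha on the
    raw p-value (the stated screen), adjusted values reported alongside.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    query = set(query_genes)
    stray = query - uni
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    results = []
    for name in sets.names():
        members = set(sets.genes_of(name)) & uni
        overlap = len(members & query)
        # upper tail P[X >= overlap]
        p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(members), len(query)))
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap=overlap,
                set_size=len(members),
                query_size=len(query),
                universe_size=len(uni),
                p_value=min(p, 1.0),
            )
        )
    if results:
        adj = bh_adjust([r.p_value for r in results])
        for r, pa in zip(results, adj):
            r.p_adjusted = float(pa)
            r.significant = bool(r.p_value < alpha)
    return results


def significant_sets(
    results: Sequence[EnrichmentResult], sets: GeneSetCollection
) -> GeneSetCollection:
    out = GeneSetCollection()
    for r in results:
        if r.significant:
            out.add(r.set_name, sets.sets[r.set_name].description, sets.genes_of(r.set_name))
    return out


def binary_set_features(
    mutations: Sequence[MutationRecord],
    samples: Sequence[str],
    gene_sets: GeneSetCollection,
) -> pd.DataFrame:
    """0/1 feature per gene set: 1 iff the patient has a mutation in any
    member gene.  Row order follows ``samples`` so the table aligns with
    the expression feature table; patients without mutation data get
    all-zero rows.
    """
    by_gene = samples_with_mutation(mutations)
    features = pd.DataFrame(0, index=list(samples), columns=gene_sets.names(), dtype=int)
    for name in gene_sets.names():
        carriers: set[str] = set()
        for gene in gene_sets.genes_of(name):
            carriers |= by_gene.get(gene, set())
        if not carriers:
            warnings.warn(f"gene set {name!r} has no mutated gene in the cohort")
        features.loc[features.index.isin(carriers), name] = 1
    return features


def passes_univariate_gate(
    p_value: float,
    hazard_ratio: float,
    alpha: float = COX_ALPHA,
    hr_threshold: float = HR_THRESHOLD,
) -> bool:
    """Strict survival-relevance gate: p < alpha AND HR > hr_threshold.

    Boundary values fail.  The harmful-direction asymmetry (only HR above
    the threshold is kept) is intentional.
    """
    return p_value < alpha and hazard_ratio > hr_threshold


def filter_features_univariate(
    features: pd.DataFrame,
    survival: SurvivalTable,
    alpha: float = COX_ALPHA,
    hr_threshold: float = HR_THRESHOLD,
) -> pd.DataFrame:
    """Keep feature columns passing the strict univariate Cox gate."""
    keep = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features are simply dropped
        for col in features.columns:
            res = cox_univariate(features[col].to_numpy(dtype=float), survival, name=str(col))
            if passes_univariate_gate(res.p_value, res.hazard_ratio, alpha, hr_threshold):
                keep.append(col)
    return features[keep]


def univariate_screen(
    features: pd.DataFrame, survival: SurvivalTable
) -> pd.DataFrame:
    """Univariate Cox results for every feature column (coef, HR, p)."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for col in features.columns:
            r = cox_univariate(features[col].to_numpy(dtype=float), survival, name=str(col))
            rows.append(
                {"feature": str(col), "coef": r.coef, "hazard_ratio": r.hazard_ratio,
                 "p_value": r.p_value}
            )
    return pd.DataFrame(rows).set_index("feature")


def combined_model(
    expr_features: pd.DataFrame,
    mut_features: pd.DataFrame,
    survival: SurvivalTable,
    seed: int = 0,
    scale_binary: bool = True,
) -> RiskModelEvaluation:
    """Risk model over normalized expression features + binary set features.

    The two tables must cover the same samples in the same order; an empty
    mutation table reduces to the expression-only model.

    With ``scale_binary`` (default), each binary column is rescaled to the
    mean standard deviation of the normalized expression columns before
    clustering.  A raw 0/1 column has sd ~0.5 while a min-max-normalized
    expression column typically spreads far less, so unscaled binary
    features would dominate the Euclidean k-means geometry and a single
    weakly informative set feature could override the whole expression
    signature.
    """
    if mut_features.shape[1] and list(expr_features.index) != list(mut_features.index):
        diff = set(expr_features.index).symmetric_difference(mut_features.index)
        raise ValueError(f"sample mismatch between feature tables: {sorted(diff)[:5]}")
    normalized = minmax_normalize(expr_features)
    if mut_features.shape[1]:
        binary = mut_features.astype(float)
        if scale_binary:
            target_sd = float(normalized.std(axis=0).mean())
            sds = binary.std(axis=0)
            scale = pd.Series(
                np.where(sds > 0, target_sd / sds.replace(0, 1.0), 1.0),
                index=binary.columns,
            )
            binary = binary * scale
        joint = pd.concat([normalized, binary], axis=1)
    else:
        joint = normalized
    grouping = cluster_risk_groups(joint, survival, seed=seed)
    return evaluate_risk_model(grouping, survival)
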