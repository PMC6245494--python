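"""End-to-end orchestration of the expression + mutation survival analysis.

Stage order mirrors the study workflow: differential expression (optional
stand-in screen or an external DE table) -> univariate Cox selection ->
hazard-ratio filter and/or GA subset search -> k-means risk groups ->
per-group mutation analytics (MRDS, SNV spectra, pairwise patterns) ->
gene-set enrichment -> binary functional features -> combined model.
Every stage writes a plain TSV so any of them can be replaced by an
external tool's output; a manifest records a content hash per artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import diffexpr as de_mod
from .functional import (
    binary_set_features,
    combined_model,
    enrich,
    filter_features_univariate,
    significant_sets,
    univariate_screen,
)
from .ga import GAConfig, run_ga
from .io_formats import (
    ExpressionMatrix,
    SurvivalTable,
    read_clinical,
    read_expression,
    read_gmt,
    read_maf,
    join_cohort,
)
from .mutation import (
    mutation_rates_by_group,
    mrds_scores,
    pairwise_patterns,
    patterns_to_frame,
    samples_with_mutation,
    snv_spectrum,
    top_k_by_mrds,
)
from .risk import RiskModelEvaluation, cluster_risk_groups, evaluate_risk_model, minmax_normalize

logger = logging.getLogger("survsig")


@dataclass
class PipelineConfig:
    expression_path: str
    clinical_path: str
    out_dir: str
    maf_path: Optional[str] = None
    gmt_path: Optional[str] = None
    normal_expression_path: Optional[str] = None
    de_table_path: Optional[str] = None  # external DE table alternative
    unit_tag: str = "fpkm"
    barcode_prefix_len: Optional[int] = None
    de_alpha: float = 0.01
    de_lfc: float = 2.0
    cox_alpha: float = 0.05
    hr_threshold: float = 1.221
    top_k: int = 2000
    enrich_alpha: float = 0.05
    total_samples: Optional[int] = None  # denominator for pairwise patterns
    n_top_mutated: int = 8
    cluster_seed: int = 17
    run_ga: bool = True
    ga_population_size: int = 200
    ga_mutation_rate: float = 0.01
    ga_generations: int = 100
    ga_elitism_fraction: float = 0.2
    ga_seed: int = 17

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, artifacts: dict, cause: Exception):
        self.stage = stage
        self.artifacts = dict(artifacts)
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _evaluation_row(name: str, n_features: int, ev: RiskModelEvaluation) -> dict:
    return {
        "model": name,
        "n_features": n_features,
        "c_index": ev.c_index,
        "hazard_ratio": ev.hazard_ratio,
        "cox_p": ev.cox_p,
        "logrank_p": ev.logrank_p,
    }


def _risk_model_for_genes(
    genes: Sequence[str],
    expression: ExpressionMatrix,
    survival: SurvivalTable,
    seed: int,
):
    features = expression.subset_genes(list(genes)).frame.T
    normalized = minmax_normalize(features)
    grouping = cluster_risk_groups(normalized, survival, seed=seed)
    return grouping, evaluate_risk_model(grouping, survival)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run manifest.

    The manifest maps artifact names to paths and content hashes and
    carries the final model-comparison report.  Any stage failure raises
    ``PipelineStageError`` naming the stage and the artifacts written so
    far.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "load_inputs"

    def emit(name: str, frame: pd.DataFrame, comment: str, index: bool = True) -> None:
        path = out / f"{name}.tsv"
        with path.open("w") as fh:
            fh.write(f"# {comment}\n")
            frame.to_csv(fh, sep="\t", index=index)
        artifacts[name] = path

    try:
        expression = read_expression(config.expression_path, unit_tag=config.unit_tag)
        survival = read_clinical(config.clinical_path)
        mutations = (
            read_maf(config.maf_path, config.barcode_prefix_len)
            if config.maf_path
            else []
        )
        gene_sets = read_gmt(config.gmt_path) if config.gmt_path else None
        expression, survival, mutations, join_report = join_cohort(
            expression, survival, mutations
        )
        expression = expression.log2()

        stage = "differential_expression"
        if config.de_table_path:
            de_frame = pd.read_csv(config.de_table_path, sep="\t", comment="#")
            de_genes = de_frame.loc[de_frame["significant"].astype(bool), "gene"].tolist()
        elif config.normal_expression_path:
            normal = read_expression(
                config.normal_expression_path, unit_tag=config.unit_tag
            )
            results = de_mod.differential_expression(
                expression, normal.log2(), alpha=config.de_alpha,
                lfc_threshold=config.de_lfc,
            )
            de_frame = de_mod.de_results_to_frame(results)
            emit("de_table", de_frame, "Welch t DE screen on log2(x+1)", index=False)
            de_genes = de_mod.significant_genes(results)
        else:
            de_genes = expression.gene_ids
        de_genes = [g for g in de_genes if g in set(expression.gene_ids)]
        if not de_genes:
            raise ValueError("no genes passed the differential-expression gate")

        stage = "univariate_selection"
        de_features = expression.subset_genes(de_genes).frame.T
        screen = univariate_screen(de_features, survival)
        emit("univariate_cox", screen, "univariate Cox per DE gene")
        univ_genes = screen.index[screen["p_value"] < config.cox_alpha].tolist()
        if not univ_genes:
            raise ValueError("no genes significant in the univariate Cox screen")
        hr_genes = screen.index[
            (screen["p_value"] < config.cox_alpha)
            & (screen["hazard_ratio"] > config.hr_threshold)
        ].tolist()

        stage = "risk_models_expression"
        report_rows = []
        grouping_univ, ev_univ = _risk_model_for_genes(
            univ_genes, expression, survival, config.cluster_seed
        )
        report_rows.append(
            _evaluation_row("univariate_significant", len(univ_genes), ev_univ)
        )
        grouping_hr = None
        if hr_genes:
            grouping_hr, ev_hr = _risk_model_for_genes(
                hr_genes, expression, survival, config.cluster_seed
            )
            report_rows.append(_evaluation_row("hr_filtered", len(hr_genes), ev_hr))

        stage = "ga_selection"
        ga_genes: list[str] = []
        grouping_ga = None
        if config.run_ga:
            candidates = expression.subset_genes(univ_genes).frame.T
            ga_conf = GAConfig(
                chromosome_length=len(univ_genes),
                population_size=config.ga_population_size,
                mutation_rate=config.ga_mutation_rate,
                generations=config.ga_generations,
                elitism_fraction=config.ga_elitism_fraction,
                seed=config.ga_seed,
                cluster_seed=config.cluster_seed,
            )
            # seed the population with the full candidate set and the
            # HR-filtered subset so the GA result dominates both
            seeds_chroms = [np.ones(len(univ_genes), dtype=np.int8)]
            if hr_genes:
                hr_mask = np.isin(np.array(univ_genes), np.array(hr_genes)).astype(np.int8)
                seeds_chroms.append(hr_mask)
            ga_result = run_ga(
                candidates, survival, ga_conf, initial_chromosomes=seeds_chroms
            )
            ga_genes = [univ_genes[i] for i in ga_result.selected_indices]
            emit(
                "ga_trajectory",
                ga_result.fitness_trajectory,
                "GA best/mean fitness per generation",
                index=False,
            )
            pd.Series(ga_genes, name="gene").to_csv(
                out / "ga_genes.tsv", sep="\t", index=False
            )
            artifacts["ga_genes"] = out / "ga_genes.tsv"
            grouping_ga, ev_ga = _risk_model_for_genes(
                ga_genes, expression, survival, config.cluster_seed
            )
            report_rows.append(_evaluation_row("ga_selected", len(ga_genes), ev_ga))

        # the grouping driving the mutation analysis (HR-filtered set when
        # available, otherwise the full univariate set)
        grouping = grouping_hr if grouping_hr is not None else grouping_univ
        grouping_frame = grouping.labels.rename("risk_group").to_frame()
        emit("risk_groups", grouping_frame, "per-sample high/low risk labels")

        stage = "mutation_patterns"
        mut_universe: list[str] = []
        top_mrds_genes: list[str] = []
        if mutations:
            rates = mutation_rates_by_group(mutations, grouping)
            rates = rates.assign(mrds=mrds_scores(rates))
            emit("mutation_rates", rates, "per-group gene mutation rates + MRDS")
            top_mrds_genes = top_k_by_mrds(rates, k=config.top_k)
            fractions, spectrum_tests = snv_spectrum(mutations, grouping)
            emit("snv_spectrum_tests", spectrum_tests, "per-type group Welch t-tests")
            by_gene = samples_with_mutation(mutations)
            top_mutated = sorted(by_gene, key=lambda g: (-len(by_gene[g]), g))[
                : config.n_top_mutated
            ]
            total = config.total_samples or len({m.sample_id for m in mutations})
            patterns = pairwise_patterns(mutations, top_mutated, total)
            emit(
                "pairwise_patterns",
                patterns_to_frame(patterns),
                "pairwise mutual exclusivity / co-occurrence",
                index=False,
            )
            mut_universe = sorted(by_gene)

        stage = "functional_features"
        mut_features = pd.DataFrame(index=expression.sample_ids)
        if mutations and gene_sets is not None and top_mrds_genes:
            universe = mut_universe
            query = [g for g in top_mrds_genes if g in set(universe)]
            enrichment = enrich(query, gene_sets, universe, alpha=config.enrich_alpha)
            enrich_frame = pd.DataFrame(
                [dataclasses.asdict(r) for r in enrichment]
            ).set_index("set_name")
            emit("enrichment", enrich_frame, "hypergeometric set over-representation")
            sig_sets = significant_sets(enrichment, gene_sets)
            if len(sig_sets):
                candidates = binary_set_features(
                    mutations, expression.sample_ids, sig_sets
                )
                mut_features = filter_features_univariate(
                    candidates, survival,
                    alpha=config.cox_alpha, hr_threshold=config.hr_threshold,
                )
                emit(
                    "functional_features",
                    mut_features,
                    "binary gene-set features passing the univariate filter",
                )
                if mut_features.shape[1]:
                    grouping_fs = cluster_risk_groups(
                        mut_features.astype(float), survival, seed=config.cluster_seed
                    )
                    ev_fs = evaluate_risk_model(grouping_fs, survival)
                    report_rows.append(
                        _evaluation_row(
                            "functional_sets", mut_features.shape[1], ev_fs
                        )
                    )

        stage = "combined_model"
        combo_genes = ga_genes if ga_genes else (hr_genes or univ_genes)
        expr_features = expression.subset_genes(combo_genes).frame.T
        ev_comb = combined_model(
            expr_features, mut_features, survival, seed=config.cluster_seed
        )
        report_rows.append(
            _evaluation_row(
                "combined", len(combo_genes) + mut_features.shape[1], ev_comb
            )
        )

        stage = "report"
        report = pd.DataFrame(report_rows)
        emit("model_report", report, "C-index of models on different feature types",
             index=False)
        manifest = {
            "artifacts": {
                name: {"path": str(path), "sha256": _sha256(path)}
                for name, path in artifacts.items()
            },
            "n_samples": survival.n,
            "n_common_samples": len(join_report.common_samples),
            "gene_counts": {
                "differential": len(de_genes),
                "univariate_significant": len(univ_genes),
                "hr_filtered": len(hr_genes),
                "ga_selected": len(ga_genes),
                "functional_sets": int(mut_features.shape[1]),
            },
            "report": report.to_dict(orient="records"),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, {k: str(v) for k, v in artifacts.items()}, exc) from exc


def apply_signature(
    gene_list: Sequence[str],
    expression: ExpressionMatrix,
    survival: SurvivalTable,
    seed: int = 17,
) -> tuple[RiskModelEvaluation, int]:
    """Evaluate a gene signature on an independent cohort.

    Restricts the signature to the genes present in the new cohort
    (erroring on an empty intersection), re-normalizes within the cohort,
    clusters and evaluates.  Returns the evaluation and the intersection
    size.
    """
    present = [g for g in gene_list if g in set(expression.gene_ids)]
    if not present:
        raise ValueError("no signature genes present in the validation cohort")
    if len(present) < len(gene_list):
        logger.info(
            "signature intersection: %d of %d genes present",
            len(present),
            len(gene_list),
        )
    expression, survival, _, _ = join_cohort(expression, survival)
    features = expression.log2().subset_genes(present).frame.T
    normalized = minmax_normalize(features)
    grouping = cluster_risk_groups(normalized, survival, seed=seed)
    return evaluate_risk_model(grouping, survival), len(present)
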