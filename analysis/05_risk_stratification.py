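"""Stratify patients into high/low survival-risk groups and evaluate.

Builds the cluster-then-Cox risk model for each gene signature (broad
univariate, HR-filtered, GA-selected), writes the per-sample grouping of
the HR-filtered model (used downstream for mutation analytics) and the
per-group Kaplan-Meier curves, and compares the models' C-indices.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from common import RESULTS, load_cohort, load_truth, save
from survsig.risk import cluster_risk_groups, evaluate_risk_model, minmax_normalize

CLUSTER_SEED = 17


def main() -> None:
    expression, survival, _, _ = load_cohort()
    signatures = {
        "univariate_significant": "03_selected_genes.tsv",
        "hr_filtered": "03_hr_filtered_genes.tsv",
        "ga_selected": "04_ga_genes.tsv",
    }
    truth_frame, _ = load_truth()
    truth = truth_frame.set_index("sample_id")["true_group"]
    rows = []
    for name, path in signatures.items():
        genes = pd.read_csv(RESULTS / path, sep="\t")["gene"].tolist()
        features = minmax_normalize(expression.subset_genes(genes).frame.T)
        grouping = cluster_risk_groups(features, survival, seed=CLUSTER_SEED)
        ev = evaluate_risk_model(grouping, survival)
        agreement = float((grouping.labels == truth).mean())
        rows.append(
            {"model": name, "n_genes": len(genes), "c_index": ev.c_index,
             "hazard_ratio": ev.hazard_ratio, "logrank_p": ev.logrank_p,
             "truth_agreement": agreement}
        )
        if name == "hr_filtered":
            save(grouping.labels.rename("risk_group").to_frame(),
                 "05_risk_groups.tsv", "per-sample high/low risk labels "
                 "(HR-filtered signature)")
            for label, curve in (("high", ev.km_high), ("low", ev.km_low)):
                km = pd.DataFrame(
                    {"time_days": curve.event_times,
                     "survival_probability": curve.survival_probabilities,
                     "n_at_risk": curve.n_at_risk}
                )
                save(km, f"05_km_{label}.tsv",
                     f"Kaplan-Meier curve, {label}-risk group", index=False)
    report = pd.DataFrame(rows)
    save(report, "05_risk_models.tsv", "risk-model comparison per signature",
         index=False)
    print(report.to_string(index=False, float_format=lambda v: f"{v:.4f}"))


if __name__ == "__main__":
    main()
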