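"""Select survival-associated genes from the differential set.

Univariate Cox per DE gene, keeping p < 0.05 (the broad signature), then
the stricter hazard-ratio filter HR > 1.221 (the harmful-direction
signature).  Reports how many planted risk genes survive each gate.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from common import RESULTS, load_cohort, load_truth, save
from survsig.functional import univariate_screen

COX_ALPHA = 0.05
HR_THRESHOLD = 1.221


def main() -> None:
    expression, survival, _, _ = load_cohort()
    de = pd.read_csv(RESULTS / "02_de_table.tsv", sep="\t", comment="#")
    de_genes = de.loc[de["significant"], "gene"].tolist()
    features = expression.subset_genes(de_genes).frame.T
    screen = univariate_screen(features, survival)
    save(screen, "03_univariate_cox.tsv", "univariate Cox per DE gene")
    selected = screen.index[screen["p_value"] < COX_ALPHA].tolist()
    hr_filtered = screen.index[
        (screen["p_value"] < COX_ALPHA) & (screen["hazard_ratio"] > HR_THRESHOLD)
    ].tolist()
    pd.Series(selected, name="gene").to_csv(
        RESULTS / "03_selected_genes.tsv", sep="\t", index=False
    )
    pd.Series(hr_filtered, name="gene").to_csv(
        RESULTS / "03_hr_filtered_genes.tsv", sep="\t", index=False
    )
    _, meta = load_truth()
    planted = set(meta.get("risk_genes", []))
    print(f"{len(selected)} of {len(de_genes)} DE genes significant in "
          f"univariate Cox (p<{COX_ALPHA}); {len(hr_filtered)} also have "
          f"HR>{HR_THRESHOLD}")
    print(f"planted risk genes recovered: {len(planted & set(selected))} "
          f"of {len(planted)} (broad), {len(planted & set(hr_filtered))} (HR-filtered)")


if __name__ == "__main__":
    main()
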