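"""Screen tumor-vs-normal differential expression.

Applies the Welch-t / BH screen on log2 values with the gates
adjusted p < 0.01 and |log2 FC| > 2, and checks how many of the planted
differential genes are caught.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from common import COHORT_DIR, load_truth, save
from survsig.diffexpr import de_results_to_frame, differential_expression, significant_genes
from survsig.io_formats import read_expression


def main() -> None:
    tumor = read_expression(COHORT_DIR / "expression.tsv", unit_tag="log2")
    normal = read_expression(COHORT_DIR / "normal_expression.tsv", unit_tag="log2")
    results = differential_expression(tumor, normal)
    frame = de_results_to_frame(results)
    save(frame, "02_de_table.tsv", "Welch t DE screen, adj p<0.01 & |log2FC|>2",
         index=False)
    sig = significant_genes(results)
    _, meta = load_truth()
    print(f"{len(sig)} of {len(frame)} genes pass the DE gate")
    print(f"planted risk genes among them: "
          f"{len(set(meta.get('risk_genes', [])) & set(sig))} of "
          f"{len(meta.get('risk_genes', []))}")


if __name__ == "__main__":
    main()
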