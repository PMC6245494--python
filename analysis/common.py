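"""Shared paths and cohort-loading helpers for the numbered analysis drivers.

The drivers form a sequence: 01 simulates a cohort into results/cohort/,
later steps read it plus each other's tables from results/.  Every
computation lives in the survsig library; these scripts only wire stages
together and narrate what they find.
"""

from pathlib import Path

import pandas as pd

from survsig.io_formats import read_clinical, read_expression, read_gmt, read_maf

RESULTS = Path(__file__).resolve().parents[1] / "results"
COHORT_DIR = RESULTS / "cohort"

#: Conditions of the demonstration cohort (chosen once; see docs/methods.md).
COHORT_CONDITIONS = dict(
    n_samples=400,
    n_genes=2000,
    n_risk_genes=15,
    n_diff_mut_genes=40,
    diff_mut_min_base_rate=0.05,
    hazard_beta=1.2,
    n_normal_samples=60,
    n_de_genes=40,
    seed=20260920,
)


def load_cohort():
    expression = read_expression(COHORT_DIR / "expression.tsv", unit_tag="log2")
    survival = read_clinical(COHORT_DIR / "clinical.tsv")
    mutations = read_maf(COHORT_DIR / "mutations.maf")
    gene_sets = read_gmt(COHORT_DIR / "gene_sets.gmt")
    return expression, survival, mutations, gene_sets


def load_truth() -> tuple[pd.DataFrame, dict]:
    path = COHORT_DIR / "ground_truth.tsv"
    meta = {}
    for line in path.read_text().splitlines():
        if line.startswith("# ") and ":" in line:
            key, _, value = line[2:].partition(":")
            meta[key.strip()] = [g for g in value.strip().split(",") if g]
        if not line.startswith("#"):
            break
    frame = pd.read_csv(path, sep="\t", comment="#")
    return frame, meta


def save(frame: pd.DataFrame, name: str, comment: str, index: bool = True) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / name
    with path.open("w") as fh:
        fh.write(f"# {comment}\n")
        frame.to_csv(fh, sep="\t", index=index)
    return path
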