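"""Seed-sweep benchmark of the full modelling chain.

Repeats the realistic analysis path on 20 independently drawn cohorts
with planted signals and summarizes how often the risk grouping recovers
the true groups and whether adding mutation-derived features costs
C-index.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from common import save
from survsig.benchmarks import risk_recovery_benchmark


def main() -> None:
    bench = risk_recovery_benchmark(n_seeds=20, base_seed=1)
    save(bench, "09_recovery_benchmark.tsv",
         "per-seed recovery statistics of the full modelling chain",
         index=False)
    agree = (bench["grouping_agreement"] >= 0.8).mean()
    not_worse = (
        bench["c_index_combined"] >= bench["c_index_expression"] - 0.01
    ).mean()
    print(f"risk grouping matches the true groups for >=80% of samples in "
          f"{agree:.0%} of seeds (mean agreement "
          f"{bench['grouping_agreement'].mean():.3f})")
    print(f"combined model within 0.01 of expression-only C-index in "
          f"{not_worse:.0%} of seeds "
          f"(mean C: expression {bench['c_index_expression'].mean():.4f}, "
          f"combined {bench['c_index_combined'].mean():.4f})")


if __name__ == "__main__":
    main()
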