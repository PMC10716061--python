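"""Reproduce the tb statistic and 95% CI for both mock-juror experiments.

Runs the pooled-SE Wald analysis on the embedded change counts (after the
per-condition exclusions) and writes a table to results/change_statistics.csv.
Finding: Experiment 1 gives tb = -0.02, CI [-0.10, 0.06] (no violation);
Experiment 2 gives tb = 0.09, CI [-0.01, 0.19] (a positive trend whose CI
just includes 0).
"""

from pathlib import Path

import pandas as pd

from temporal_bell import datasets
from temporal_bell.tb_inference import tb_estimate

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for exp in datasets.EXPERIMENTS:
        counts = datasets.condition_counts(exp)
        est = tb_estimate(counts)
        rounded = est.rounded()
        rows.append(
            {
                "experiment": exp,
                **{
                    f"{cond}": f"{chg}/{tot}"
                    for cond, (chg, tot) in counts.counts.items()
                },
                "tb": rounded["tb"],
                "ci_lower": rounded["ci_lower"],
                "ci_upper": rounded["ci_upper"],
                "verdict": est.verdict,
            }
        )
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "change_statistics.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
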