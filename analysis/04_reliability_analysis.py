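"""Test-retest reliability of the questionnaire (occasion 1 vs occasion 2).

Per behaviour: occasion means and SDs, ICC(A,1) and ICC(C,1) with
F-based 95% CIs, Spearman's rho with a 2000-resample bootstrap CI, and
the mean test-retest difference with its CI.
"""

from pathlib import Path

import pandas as pd

from timeuse24.pipeline import StudyConfig, run_reliability

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 2022


def main() -> None:
    dabq1 = pd.read_csv(BASE / "dabq1_scored.tsv", sep="\t")
    dabq2 = pd.read_csv(BASE / "dabq2_scored.tsv", sep="\t")
    report, pairs = run_reliability(dabq1, dabq2, StudyConfig(seed=SEED))
    report.to_csv(BASE / "reliability.tsv", sep="\t", index=False)
    pairs.to_csv(BASE / "reliability_pairs.tsv", sep="\t", index=False)

    view = report[["behaviour", "dabq1_mean", "dabq2_mean", "icc_a1", "icc_a1_lo",
                   "icc_a1_hi", "icc_c1", "rho", "mean_diff", "n"]]
    print(view.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
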