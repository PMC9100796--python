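"""Convergent validity: questionnaire occasion 2 vs the device week.

Per behaviour: ICCs, Spearman's rho, the Bland-Altman mean difference
(questionnaire minus device) with its CI, 1.96-SD limits of agreement
with CIs, and the proportional-bias slope of differences on pair means.
Also writes the per-participant (mean, difference) pairs for plotting.
"""

from pathlib import Path

import pandas as pd

from timeuse24.pipeline import StudyConfig, run_validity

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 2022


def main() -> None:
    dabq2 = pd.read_csv(BASE / "dabq2_scored.tsv", sep="\t")
    device = pd.read_csv(BASE / "device_weekly.tsv", sep="\t")
    report, pairs = run_validity(dabq2, device, StudyConfig(seed=SEED))
    report.to_csv(BASE / "validity.tsv", sep="\t", index=False)
    pairs.to_csv(BASE / "validity_pairs.tsv", sep="\t", index=False)

    view = report[["behaviour", "dabq2_mean", "device_mean", "icc_a1", "icc_c1",
                   "rho", "mean_diff", "loa_lower", "loa_upper",
                   "prop_bias_beta", "prop_bias_p", "n"]]
    print(view.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
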