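"""Score both questionnaire occasions into closed 24-h compositions.

Reads the simulated response table, applies the scoring rules (sleep
from time in bed with latency/WASO/naps; SB and MVPA as domain sums;
LPA as the 24-h remainder) and writes one composition table per
occasion, reporting how many records were internally inconsistent.
"""

from pathlib import Path

import pandas as pd

from timeuse24.dabq import score_table

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    responses = pd.read_csv(BASE / "simulated" / "dabq_responses.tsv", sep="\t")
    scored = score_table(responses)
    for occ in (1, 2):
        part = scored[scored["occasion"] == occ]
        part.to_csv(BASE / f"dabq{occ}_scored.tsv", sep="\t", index=False)
        means = part[part["valid"]][["sleep", "sb", "lpa", "mvpa"]].mean()
        print(
            f"occasion {occ}: {len(part)} scored, {int((~part['valid']).sum())} invalid; "
            "mean min/day "
            + ", ".join(f"{b}={means[b]:.0f}" for b in ("sleep", "sb", "lpa", "mvpa"))
        )


if __name__ == "__main__":
    main()
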