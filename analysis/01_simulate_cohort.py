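"""Simulate the study cohort: questionnaires, device weeks, diaries.

Draws 126 participants with latent weekly 24-h compositions, emits two
occasions of questionnaire responses, a seven-day device event stream
with nightly sleep diaries, and a ground-truth table (written for
evaluation only; no downstream step reads it).
"""

from pathlib import Path

import pandas as pd

from timeuse24.activpal import diaries_to_frame, events_to_frame
from timeuse24.dabq import responses_to_frame
from timeuse24.synthetic import (
    CohortConfig,
    generate_cohort,
    generate_dabq_responses,
    generate_event_stream,
)

SEED = 2022
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    cfg = CohortConfig(seed=SEED)
    cohort = generate_cohort(cfg)
    responses, events, diaries, truth_rows = [], {}, {}, []
    for t in cohort:
        responses += [generate_dabq_responses(t, occ, cfg) for occ in (1, 2)]
        stream = generate_event_stream(t, cfg)
        events[t.participant_id] = stream.events
        diaries[t.participant_id] = stream.diaries
        truth_rows.append(
            {"participant_id": t.participant_id, **t.latent_composition.as_dict(),
             "workdays_per_week": t.workdays_per_week, "shift_work": t.shift_work}
        )

    OUT.mkdir(parents=True, exist_ok=True)
    responses_to_frame(responses).to_csv(OUT / "dabq_responses.tsv", sep="\t", index=False)
    ev = events_to_frame(events)
    ev.to_csv(OUT / "events.tsv", sep="\t", index=False)
    diaries_to_frame(diaries).to_csv(OUT / "diaries.tsv", sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(OUT / "ground_truth.tsv", sep="\t", index=False)

    print(f"simulated {len(cohort)} participants (seed {SEED})")
    print(f"  {len(responses)} questionnaire records, {len(ev)} device events")
    print(f"  -> {OUT}")


if __name__ == "__main__":
    main()
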