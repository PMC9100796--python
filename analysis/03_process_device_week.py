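"""Process device event streams and diaries into weekly compositions.

Applies the full per-day chain — time-in-bed detection, diary/device
sleep fusion, cadence-based waking classification, nap adjustment,
non-wear accounting and reallocation — then averages valid days
(> 20 h wear) for participants with at least five of them.
"""

from pathlib import Path

import pandas as pd

from timeuse24.activpal import (
    ProcessingConfig,
    frame_to_diaries,
    frame_to_events,
    process_participant,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = ProcessingConfig()
    events = frame_to_events(pd.read_csv(BASE / "simulated" / "events.tsv", sep="\t"))
    diaries = frame_to_diaries(pd.read_csv(BASE / "simulated" / "diaries.tsv", sep="\t"), config)

    weekly_rows, daily_rows = [], []
    for pid, evs in events.items():
        days = sorted({e.start.date() for e in evs if e.start.hour >= config.day_boundary_hour})
        weekly, summaries = process_participant(evs, diaries.get(pid, {}), days, config)
        weekly_rows.append(
            {"participant_id": pid, "occasion": 0, **weekly.as_dict(), "valid": weekly.valid}
        )
        daily_rows += [
            {"participant_id": pid, "date": s.date.isoformat(),
             "sleep": round(s.sleep, 1), "sb": round(s.sb, 1), "lpa": round(s.lpa, 1),
             "mvpa": round(s.mvpa, 1), "nonwear": round(s.nonwear, 1),
             "wear": round(s.wear, 1), "valid": s.valid, "flags": ";".join(s.flags)}
            for s in summaries
        ]

    weekly = pd.DataFrame(weekly_rows)
    daily = pd.DataFrame(daily_rows)
    weekly.to_csv(BASE / "device_weekly.tsv", sep="\t", index=False)
    daily.to_csv(BASE / "device_daily.tsv", sep="\t", index=False)

    n_valid_days = int(daily["valid"].sum())
    included = weekly["valid"].sum()
    print(f"{len(daily)} monitored days, {n_valid_days} valid (> 20 h wear)")
    print(f"{included}/{len(weekly)} participants with >= {config.min_valid_days} valid days")
    means = weekly[weekly["valid"]][["sleep", "sb", "lpa", "mvpa"]].mean()
    print("device mean min/day " + ", ".join(f"{b}={means[b]:.0f}" for b in means.index))


if __name__ == "__main__":
    main()
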