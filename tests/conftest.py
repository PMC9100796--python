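from __future__ import annotations

from datetime import date, datetime, timedelta

import pytest

from timeuse24.activpal import ActivityClass, EventRecord
from timeuse24.synthetic import CohortConfig

BASE_DATE = date(2022, 3, 7)  # a Monday; device days run noon-to-noon


def ts(hhmm: str, day_offset: int = 0) -> datetime:
    """Timestamp on the fixture night: evening hours on BASE_DATE, morning next day."""
    h, m = map(int, hhmm.split(":"))
    d = day_offset + (1 if h < 12 else 0)
    return datetime(BASE_DATE.year, BASE_DATE.month, BASE_DATE.day, h, m) + timedelta(days=d)


CLASSES = {
    "sit": ActivityClass.SITTING_LYING,
    "stand": ActivityClass.STANDING,
    "step": ActivityClass.STEPPING,
}


def build_events(bouts: list[tuple[str, str, str]], cadence: float = 80.0) -> list[EventRecord]:
    """Events from (start hh:mm, end hh:mm, class) triples on the fixture night."""
    events = []
    for start, end, cls in bouts:
        s, e = ts(start), ts(end)
        events.append(
            EventRecord(
                s,
                (e - s).total_seconds(),
                CLASSES[cls],
                cadence if cls == "step" else 0.0,
            )
        )
    return events


@pytest.fixture
def zero_noise_config() -> CohortConfig:
    """Every stochastic distortion off: generators become exact inverses."""
    return CohortConfig(
        n_participants=12,
        test_retest_error_sd=0.0,
        device_error_sd=0.0,
        device_bias=0.0,
        nonwear_rate=0.0,
        nap_probability=0.0,
        diary_jitter_sd=0.0,
        onset_burst_probability=0.0,
        seed=42,
    )
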