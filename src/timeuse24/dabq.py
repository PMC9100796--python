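"""Scoring of DABQ-style questionnaire responses into a 24-h composition.

The Daily Activity Behaviours Questionnaire (DABQ) asks, for a usual week,
about sleep (bed/rise clock times, sleep latency, wake after sleep onset,
napping) and about domain-specific sedentary behaviour and physical
activity across occupational, commuting and other non-occupational
domains.  Scoring rules:

* sleep = time in bed (clock span, overnight wrap) - latency - WASO
  + weekly nap minutes / 7;
* SB = occupational SB (workplace span x VAS proportion x workdays/7)
  + commuting SB (daily commute x VAS) + other SB (already daily);
* MVPA = occupational (yes/no gated, days x duration / 7)
  + commuting (daily) + other (days x duration / 7);
* LPA = the 24-h remainder.

A negative remainder marks the record invalid (over-reporting) rather than
being truncated, so downstream analyses can exclude it with a diagnostic.
Day-weighting conventions (which items are "already daily") are explicit
in the field schema below and configurable where noted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .composition import TimeUseComposition, close_composition

#: resolution at which visual-analogue proportions are stored
VAS_RESOLUTION = 0.01


def quantize_vas(value: float) -> float:
    """Snap a visual-analogue proportion to the instrument's 0.01 grid."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"VAS proportion must be in [0, 1], got {value}")
    return round(value / VAS_RESOLUTION) * VAS_RESOLUTION


def clock_span_minutes(start_hhmm: str, end_hhmm: str) -> float:
    """Minutes from ``start`` to ``end`` on the clock, wrapping overnight.

    ``end <= start`` is taken to mean the span crosses midnight (e.g. bed
    23:00, rise 07:00 -> 480 min).
    """
    sh, sm = map(int, start_hhmm.split(":"))
    eh, em = map(int, end_hhmm.split(":"))
    span = (eh * 60 + em) - (sh * 60 + sm)
    if span <= 0:
        span += 24 * 60
    return float(span)


@dataclass(frozen=True)
class DABQResponseSet:
    """One occasion's questionnaire answers for one participant.

    The instrument's full item list is not public; these fields are the
    minimal set the scoring rules consume, documented as a column
    dictionary in the I/O layer so a full instrument export can be mapped
    onto them.
    """

    participant_id: str
    occasion: int  # 1 or 2
    # sleep domain
    bed_time: str  # hh:mm
    rise_time: str  # hh:mm; <= bed_time means next-day rise
    sleep_latency: float  # min
    waso: float  # min, wake after sleep onset
    nap_days: int  # 0-7
    nap_duration: float  # min per nap day
    # occupational domain
    workdays: int  # 0-7
    work_arrival: str  # hh:mm
    work_departure: str  # hh:mm
    occupational_sb_vas: float  # proportion of workplace time sitting
    occupational_mvpa_flag: bool
    occupational_mvpa_days: int
    occupational_mvpa_duration: float  # min/day on those days
    # commuting domain (daily averages)
    commute_duration: float  # min/day
    commute_sb_vas: float
    commute_mvpa_duration: float  # min/day
    # other non-occupational domain
    other_sb_duration: float  # min/day
    other_mvpa_days: int
    other_mvpa_duration: float  # min/day on those days

    def __post_init__(self):
        if self.occasion not in (1, 2):
            raise ValueError("occasion must be 1 or 2")
        for name in ("occupational_sb_vas", "commute_sb_vas"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("nap_days", "workdays", "occupational_mvpa_days", "other_mvpa_days"):
            v = getattr(self, name)
            if not 0 <= v <= 7:
                raise ValueError(f"{name} must be in [0, 7], got {v}")
        for name in (
            "sleep_latency", "waso", "nap_duration", "occupational_mvpa_duration",
            "commute_duration", "commute_mvpa_duration", "other_sb_duration",
            "other_mvpa_duration",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class ScoringError(ValueError):
    """An internally inconsistent response that cannot be scored."""


def score_sleep(r: DABQResponseSet) -> float:
    """Daily sleep minutes from time in bed, latency, WASO and naps."""
    tib = clock_span_minutes(r.bed_time, r.rise_time)
    if r.sleep_latency + r.waso >= tib:
        raise ScoringError(
            f"latency + WASO ({r.sleep_latency + r.waso:.0f} min) >= time in bed "
            f"({tib:.0f} min) for {r.participant_id}"
        )
    nap_daily = r.nap_days * r.nap_duration / 7.0
    return tib - r.sleep_latency - r.waso + nap_daily


def score_sb(r: DABQResponseSet) -> float:
    """Daily sedentary minutes summed over the three domains."""
    if r.workdays > 0:
        span = clock_span_minutes(r.work_arrival, r.work_departure)
        occupational = span * r.occupational_sb_vas * r.workdays / 7.0
    else:
        occupational = 0.0
    commuting = r.commute_duration * r.commute_sb_vas
    return occupational + commuting + r.other_sb_duration


def score_mvpa(r: DABQResponseSet) -> float:
    """Daily MVPA minutes summed over the three domains."""
    if r.occupational_mvpa_flag:
        occupational = r.occupational_mvpa_days * r.occupational_mvpa_duration / 7.0
    else:
        occupational = 0.0
    other = r.other_mvpa_days * r.other_mvpa_duration / 7.0
    return occupational + r.commute_mvpa_duration + other


def score_composition(r: DABQResponseSet) -> TimeUseComposition:
    """Score one response set into a closed composition (LPA = remainder)."""
    try:
        sleep = score_sleep(r)
    except ScoringError:
        return TimeUseComposition(0, 0, 0, 0, valid=False, flags=("sleep_scoring_error",))
    sb = score_sb(r)
    mvpa = score_mvpa(r)
    return close_composition(sleep, sb, mvpa)


# ---------------------------------------------------------------------------
# tabular I/O

RESPONSE_COLUMNS = [f.name for f in DABQResponseSet.__dataclass_fields__.values()]  # type: ignore[attr-defined]


def responses_to_frame(responses: list[DABQResponseSet]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in responses], columns=RESPONSE_COLUMNS)


def frame_to_responses(df: pd.DataFrame) -> list[DABQResponseSet]:
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        d["occupational_mvpa_flag"] = bool(d["occupational_mvpa_flag"])
        for c in ("occasion", "nap_days", "workdays", "occupational_mvpa_days", "other_mvpa_days"):
            d[c] = int(d[c])
        d["participant_id"] = str(d["participant_id"])
        out.append(DABQResponseSet(**d))
    return out


def score_table(df: pd.DataFrame) -> pd.DataFrame:
    """Score a one-row-per-participant-occasion response table.

    Returns columns (participant_id, occasion, sleep, sb, lpa, mvpa, valid).
    """
    rows = []
    for r in frame_to_responses(df):
        comp = score_composition(r)
        rows.append(
            {
                "participant_id": r.participant_id,
                "occasion": r.occasion,
                **comp.as_dict(),
                "valid": comp.valid,
            }
        )
    return pd.DataFrame(rows)
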