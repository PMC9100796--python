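"""Processing of thigh-worn device event streams into daily behaviour minutes.

The activPAL family of thigh-worn inclinometers exports an "events" file:
consecutive bouts classified as sitting/lying, standing or stepping, with
a stepping cadence.  This module turns such a stream, together with a
daily sleep diary, into per-day and per-week behaviour estimates:

1.  Each noon-to-noon day, the candidate time-in-bed window is the longest
    run of sitting/lying events mergeable across upright interruptions of
    at most 15 min in total.
2.  Sleep onset/offset are fused with the diary: the diary onset stands
    unless a burst of upright events occurs within the 20 min after it (in
    which case onset moves to the first sitting/lying event after that
    burst); the diary wake time stands if it precedes the first upright
    burst that follows more than one hour of sitting/lying (otherwise the
    offset is the end of the last sitting/lying event before that burst).
3.  Waking sitting/lying counts as SB; standing and sub-threshold stepping
    as LPA; stepping at or above a cadence cut-point (default 100
    steps/min, approximately the 3 MET boundary) as MVPA.
4.  Diary naps are added to sleep and deducted from SB.
5.  Gaps in the event stream are non-wear; a day is valid with more than
    20 h wear (i.e. under 4 h non-wear), and non-wear time on valid days
    is reallocated proportionally to the waking behaviours only.
6.  Weekly estimates are arithmetic means over valid days; participants
    with fewer than 5 valid days are excluded.

All internal arithmetic is in seconds; minutes appear only in reports.
A "burst of upright events" is not a published definition; the default
here (cumulative >= 60 s upright within any 5-min span) is a configurable
sensitivity knob.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from datetime import date as Date
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd

from .composition import MINUTES_PER_DAY, TimeUseComposition

logger = logging.getLogger(__name__)

DAY_SECONDS = 86400.0


class ActivityClass(enum.IntEnum):
    SITTING_LYING = 0
    STANDING = 1
    STEPPING = 2


@dataclass(frozen=True)
class EventRecord:
    """One device bout: start, duration, posture class, stepping cadence."""

    start: datetime
    duration_s: float
    activity_class: ActivityClass
    cadence: float = 0.0  # steps/min; meaningful for stepping only

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("event duration must be positive")

    @property
    def end(self) -> datetime:
        return self.start + timedelta(seconds=self.duration_s)

    @property
    def upright(self) -> bool:
        return self.activity_class != ActivityClass.SITTING_LYING


@dataclass(frozen=True)
class DiaryRecord:
    """One night's sleep diary: intended sleep onset, wake time, nap minutes."""

    date: Date
    intended_onset: datetime
    wake_time: datetime
    nap_minutes: float = 0.0

    def __post_init__(self):
        if self.wake_time <= self.intended_onset:
            raise ValueError("wake_time must be after intended_onset")
        if self.nap_minutes < 0:
            raise ValueError("nap_minutes must be non-negative")


class FusionSource(str, enum.Enum):
    DIARY = "diary"
    EVENT = "event"


@dataclass(frozen=True)
class SleepWindow:
    night_id: Date
    onset: datetime
    offset: datetime
    onset_source: FusionSource = FusionSource.EVENT
    offset_source: FusionSource = FusionSource.EVENT

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError("sleep offset must be after onset")


@dataclass(frozen=True)
class DailyBehaviourSummary:
    """One day's behaviour minutes plus wear/validity accounting."""

    date: Date
    sleep: float
    sb: float
    lpa: float
    mvpa: float
    nonwear: float
    wear: float
    valid: bool
    flags: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class ProcessingConfig:
    """Tunable processing knobs with their field-default values."""

    burst_upright_s: float = 60.0  # cumulative upright seconds ...
    burst_window_s: float = 300.0  # ... within this span => a burst
    onset_search_min: float = 20.0  # post-diary-onset window checked for bursts
    offset_prior_sitting_min: float = 60.0  # sitting/lying run qualifying a burst
    interruption_budget_min: float = 15.0  # time-in-bed merge budget
    cadence_cutpoint: float = 100.0  # steps/min ~ 3 MET boundary
    min_wear_min: float = 1200.0  # valid day: wear strictly above 20 h
    min_valid_days: int = 5
    day_boundary_hour: int = 12  # days run noon-to-noon


# ---------------------------------------------------------------------------
# helpers


def _clip_events(events: list[EventRecord], t0: datetime, t1: datetime) -> list[EventRecord]:
    """Events intersected with [t0, t1), split at the boundaries."""
    out = []
    for e in events:
        s, f = max(e.start, t0), min(e.end, t1)
        if f > s:
            out.append(EventRecord(s, (f - s).total_seconds(), e.activity_class, e.cadence))
    return out


def _sit_lie_runs(events: list[EventRecord]) -> list[tuple[datetime, datetime]]:
    """Maximal contiguous runs of sitting/lying events (no gap, no upright)."""
    runs: list[list[datetime]] = []
    for e in events:
        if not e.upright:
            if runs and runs[-1][1] == e.start:
                runs[-1][1] = e.end
            else:
                runs.append([e.start, e.end])
    return [(a, b) for a, b in runs]


def upright_bursts(
    events: list[EventRecord], config: ProcessingConfig
) -> list[datetime]:
    """Start times of upright bursts in a stream.

    A burst is anchored at an upright-event start from which cumulative
    upright time within ``burst_window_s`` reaches ``burst_upright_s``.
    Anchors inside a previously detected burst window are suppressed so
    one episode yields one anchor.
    """
    ups = [(e.start, e.end) for e in events if e.upright]
    anchors: list[datetime] = []
    for s, _ in ups:
        horizon = s + timedelta(seconds=config.burst_window_s)
        total = 0.0
        for us, ue in ups:
            lo, hi = max(us, s), min(ue, horizon)
            if hi > lo:
                total += (hi - lo).total_seconds()
        if total >= config.burst_upright_s:
            if not anchors or (s - anchors[-1]).total_seconds() > config.burst_window_s:
                anchors.append(s)
    return anchors


# ---------------------------------------------------------------------------
# operations


def detect_time_in_bed(
    events: list[EventRecord],
    day_window: tuple[datetime, datetime],
    config: ProcessingConfig = ProcessingConfig(),
) -> SleepWindow | None:
    """Longest mergeable sitting/lying block in the day window.

    Consecutive sitting/lying runs are merged across interruptions
    (upright events or wear gaps) as long as the cumulative interruption
    time stays within the budget (default 15 min).  Ties break to the
    earliest start.  Returns ``None`` when the day has no sitting/lying.
    """
    t0, t1 = day_window
    clipped = _clip_events(events, t0, t1)
    runs = _sit_lie_runs(clipped)
    if not runs:
        return None
    budget = config.interruption_budget_min * 60.0
    best: tuple[float, datetime, datetime] | None = None
    i = 0
    gap_sum = 0.0
    for j in range(len(runs)):
        if j > 0:
            gap_sum += (runs[j][0] - runs[j - 1][1]).total_seconds()
        while gap_sum > budget and i < j:
            gap_sum -= (runs[i + 1][0] - runs[i][1]).total_seconds()
            i += 1
        span = (runs[j][1] - runs[i][0]).total_seconds()
        if best is None or span > best[0]:
            best = (span, runs[i][0], runs[j][1])
    assert best is not None
    return SleepWindow(t0.date(), best[1], best[2])


def fuse_sleep_onset(
    diary: DiaryRecord | None,
    events: list[EventRecord],
    candidate: SleepWindow,
    config: ProcessingConfig = ProcessingConfig(),
) -> tuple[datetime, FusionSource]:
    """Sleep onset from diary unless contradicted by upright activity.

    The diary onset stands when no upright burst occurs in the following
    20-min window; otherwise onset is the first sitting/lying event after
    the last in-window burst.  Without a diary, the candidate window onset
    is used.
    """
    if diary is None:
        return candidate.onset, FusionSource.EVENT
    t0 = diary.intended_onset
    t1 = t0 + timedelta(minutes=config.onset_search_min)
    window_events = _clip_events(events, t0, t1 + timedelta(seconds=config.burst_window_s))
    bursts = [b for b in upright_bursts(window_events, config) if t0 <= b < t1]
    if not bursts:
        return t0, FusionSource.DIARY
    last_burst = bursts[-1]
    for e in events:
        if not e.upright and e.start >= last_burst:
            return e.start, FusionSource.EVENT
    return candidate.onset, FusionSource.EVENT


def fuse_sleep_offset(
    diary: DiaryRecord | None,
    events: list[EventRecord],
    candidate: SleepWindow,
    onset: datetime | None = None,
    config: ProcessingConfig = ProcessingConfig(),
) -> tuple[datetime, FusionSource]:
    """Sleep offset from diary unless the device shows an earlier rise.

    A qualifying burst is an upright burst immediately preceded by a
    contiguous sitting/lying run longer than one hour.  The diary wake
    time is used when it does not come after the first qualifying burst
    following sleep onset; otherwise the offset is the end of the last
    sitting/lying event before that burst.  Without a diary, the
    candidate window offset is used.
    """
    if diary is None:
        return candidate.offset, FusionSource.EVENT
    start = onset if onset is not None else candidate.onset
    tail = [e for e in events if e.end > start]
    runs = _sit_lie_runs(_clip_events(tail, start, tail[-1].end) if tail else [])
    qualifying: datetime | None = None
    min_run = config.offset_prior_sitting_min * 60.0
    for a, b in runs:
        if (b - a).total_seconds() > min_run:
            after = [e for e in tail if e.end > b]
            bursts = upright_bursts(after, config)
            bursts = [t for t in bursts if t >= b]
            if bursts:
                qualifying = bursts[0]
                break
    if qualifying is None or diary.wake_time <= qualifying:
        return diary.wake_time, FusionSource.DIARY
    last_end: datetime | None = None
    for e in tail:
        if not e.upright and e.end <= qualifying:
            last_end = e.end
    return (last_end if last_end is not None else qualifying), FusionSource.EVENT


def classify_waking(
    events: list[EventRecord],
    sleep_window: SleepWindow,
    day_window: tuple[datetime, datetime],
    config: ProcessingConfig = ProcessingConfig(),
) -> dict[str, float]:
    """Waking minutes of SB / LPA / MVPA inside the day window.

    Sitting/lying outside the sleep window is SB; standing and stepping
    below the cadence cut-point are LPA; stepping at or above it is MVPA.
    Events overlapping the sleep boundary are split at the boundary.
    """
    t0, t1 = day_window
    sb = lpa = mvpa = 0.0
    for e in _clip_events(events, t0, t1):
        for s, f in _subtract_interval(e.start, e.end, sleep_window.onset, sleep_window.offset):
            dur = (f - s).total_seconds()
            if e.activity_class == ActivityClass.SITTING_LYING:
                sb += dur
            elif e.activity_class == ActivityClass.STANDING:
                lpa += dur
            elif e.cadence >= config.cadence_cutpoint:
                mvpa += dur
            else:
                lpa += dur
    return {"sb": sb / 60.0, "lpa": lpa / 60.0, "mvpa": mvpa / 60.0}


def _subtract_interval(s, f, cut0, cut1):
    """Parts of [s, f) outside [cut0, cut1)."""
    out = []
    if s < cut0:
        out.append((s, min(f, cut0)))
    if f > cut1:
        out.append((max(s, cut1), f))
    return out


def account_nonwear(
    events: list[EventRecord],
    day_window: tuple[datetime, datetime],
    config: ProcessingConfig = ProcessingConfig(),
) -> tuple[float, float, bool]:
    """Non-wear and wear minutes in the window; valid iff wear > 20 h.

    Gaps in the event stream are non-wear time.
    """
    t0, t1 = day_window
    covered = sum(e.duration_s for e in _clip_events(events, t0, t1))
    total = (t1 - t0).total_seconds()
    nonwear = (total - covered) / 60.0
    wear = covered / 60.0
    return nonwear, wear, wear > config.min_wear_min


def adjust_naps(
    summary: DailyBehaviourSummary, diary: DiaryRecord | None
) -> DailyBehaviourSummary:
    """Move diary nap minutes from SB into sleep (total unchanged).

    If the nap exceeds the day's SB, SB is clamped at zero, only the
    available minutes are transferred, and the day is flagged.
    """
    if diary is None or diary.nap_minutes == 0:
        return summary
    nap = diary.nap_minutes
    if nap > summary.sb:
        moved = summary.sb
        return replace(
            summary,
            sleep=summary.sleep + moved,
            sb=0.0,
            flags=summary.flags + ("nap_exceeds_sb",),
        )
    return replace(summary, sleep=summary.sleep + nap, sb=summary.sb - nap)


def reallocate_nonwear(summary: DailyBehaviourSummary) -> DailyBehaviourSummary:
    """Scale waking behaviours so the day closes to 1440 min.

    Non-wear time is redistributed proportionally over SB/LPA/MVPA only;
    sleep is untouched.  A day with zero waking time cannot be
    reallocated and is invalidated.
    """
    if summary.nonwear == 0:
        return summary
    waking = summary.sb + summary.lpa + summary.mvpa
    if waking <= 0:
        return replace(summary, valid=False, flags=summary.flags + ("no_waking_time",))
    scale = (waking + summary.nonwear) / waking
    return replace(
        summary,
        sb=summary.sb * scale,
        lpa=summary.lpa * scale,
        mvpa=summary.mvpa * scale,
        nonwear=0.0,
    )


def average_week(
    summaries: list[DailyBehaviourSummary], min_valid_days: int = 5
) -> TimeUseComposition:
    """Arithmetic mean over valid days; excluded below the valid-day floor."""
    if not summaries:
        raise ValueError("no daily summaries to average")
    valid = [s for s in summaries if s.valid]
    if len(valid) < min_valid_days:
        return TimeUseComposition(
            0, 0, 0, 0, valid=False, flags=(f"only_{len(valid)}_valid_days",)
        )
    means = {
        b: float(np.mean([getattr(s, b) for s in valid]))
        for b in ("sleep", "sb", "lpa", "mvpa")
    }
    total = sum(means.values())
    # re-close tiny rounding drift through LPA
    means["lpa"] += MINUTES_PER_DAY - total
    return TimeUseComposition(**means, valid=True)


# ---------------------------------------------------------------------------
# day and participant drivers


def day_window(day: Date, config: ProcessingConfig = ProcessingConfig()):
    t0 = datetime.combine(day, time(hour=config.day_boundary_hour))
    return t0, t0 + timedelta(days=1)


def summarize_day(
    events: list[EventRecord],
    diary: DiaryRecord | None,
    day: Date,
    config: ProcessingConfig = ProcessingConfig(),
) -> DailyBehaviourSummary:
    """Full per-day pipeline: time in bed, fusion, classification, naps."""
    window = day_window(day, config)
    nonwear, wear, valid = account_nonwear(events, window, config)
    flags: tuple[str, ...] = ()
    candidate = detect_time_in_bed(events, window, config)
    if candidate is None:
        return DailyBehaviourSummary(day, 0, 0, 0, 0, nonwear, wear, False, ("no_sitting_lying",))
    onset, onset_src = fuse_sleep_onset(diary, events, candidate, config)
    offset, offset_src = fuse_sleep_offset(diary, events, candidate, onset, config)
    if offset <= onset:
        return DailyBehaviourSummary(
            day, 0, 0, 0, 0, nonwear, wear, False, ("degenerate_sleep_window",)
        )
    sleep_win = SleepWindow(day, onset, offset, onset_src, offset_src)
    sleep_min = (
        min(offset, window[1]) - max(onset, window[0])
    ).total_seconds() / 60.0
    waking = classify_waking(events, sleep_win, window, config)
    # residual (classification rounding) is absorbed by LPA before
    # non-wear accounting so the pre-reallocation identity holds
    residual = MINUTES_PER_DAY - sleep_min - sum(waking.values()) - nonwear
    summary = DailyBehaviourSummary(
        date=day,
        sleep=sleep_min,
        sb=waking["sb"],
        lpa=waking["lpa"] + residual,
        mvpa=waking["mvpa"],
        nonwear=nonwear,
        wear=wear,
        valid=valid,
        flags=flags,
    )
    summary = adjust_naps(summary, diary)
    if summary.valid:
        summary = reallocate_nonwear(summary)
    return summary


def process_participant(
    events: list[EventRecord],
    diaries: dict[Date, DiaryRecord],
    days: list[Date],
    config: ProcessingConfig = ProcessingConfig(),
) -> tuple[TimeUseComposition, list[DailyBehaviourSummary]]:
    """Per-day summaries over the measurement week and their valid-day mean."""
    summaries = [summarize_day(events, diaries.get(d), d, config) for d in days]
    weekly = average_week(summaries, config.min_valid_days)
    return weekly, summaries


# ---------------------------------------------------------------------------
# tabular I/O

EVENT_COLUMNS = [
    "participant_id",
    "start_datetime",
    "duration_s",
    "activity_class",
    "cadence_steps_per_min",
]
DIARY_COLUMNS = ["participant_id", "date", "onset", "wake", "nap_minutes"]


def events_to_frame(events_by_pid: dict[str, list[EventRecord]]) -> pd.DataFrame:
    rows = [
        {
            "participant_id": pid,
            "start_datetime": e.start.isoformat(),
            "duration_s": e.duration_s,
            "activity_class": int(e.activity_class),
            "cadence_steps_per_min": e.cadence,
        }
        for pid, evs in events_by_pid.items()
        for e in evs
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def frame_to_events(df: pd.DataFrame) -> dict[str, list[EventRecord]]:
    out: dict[str, list[EventRecord]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.participant_id), []).append(
            EventRecord(
                pd.Timestamp(row.start_datetime).to_pydatetime(),
                float(row.duration_s),
                ActivityClass(int(row.activity_class)),
                float(row.cadence_steps_per_min),
            )
        )
    for evs in out.values():
        evs.sort(key=lambda e: e.start)
    return out


def diaries_to_frame(diaries_by_pid: dict[str, dict[Date, DiaryRecord]]) -> pd.DataFrame:
    rows = [
        {
            "participant_id": pid,
            "date": d.date.isoformat(),
            "onset": d.intended_onset.strftime("%H:%M"),
            "wake": d.wake_time.strftime("%H:%M"),
            "nap_minutes": d.nap_minutes,
        }
        for pid, dmap in diaries_by_pid.items()
        for d in dmap.values()
    ]
    return pd.DataFrame(rows, columns=DIARY_COLUMNS)


def frame_to_diaries(
    df: pd.DataFrame, config: ProcessingConfig = ProcessingConfig()
) -> dict[str, dict[Date, DiaryRecord]]:
    """Parse diary rows, resolving hh:mm clock times against the night's date.

    An onset at or after the day boundary belongs to the diary date's
    evening; an earlier one (e.g. 00:30) to the following calendar day.
    Wake times before the boundary fall on the following day.
    """
    out: dict[str, dict[Date, DiaryRecord]] = {}
    for row in df.itertuples(index=False):
        d = Date.fromisoformat(str(row.date))
        oh, om = map(int, str(row.onset).split(":"))
        wh, wm = map(int, str(row.wake).split(":"))
        onset_day = d if oh >= config.day_boundary_hour else d + timedelta(days=1)
        onset = datetime.combine(onset_day, time(oh, om))
        wake_day = d + timedelta(days=1) if wh < config.day_boundary_hour else d
        wake = datetime.combine(wake_day, time(wh, wm))
        rec = DiaryRecord(d, onset, wake, float(row.nap_minutes))
        out.setdefault(str(row.participant_id), {})[d] = rec
    return out
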