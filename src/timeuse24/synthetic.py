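"""Synthetic cohorts with known ground truth.

Raw validation-study data (questionnaires, device event files, diaries)
are rarely shareable, so every downstream stage here is exercised on
simulated participants whose latent weekly 24-h composition is known:

* latent compositions are drawn on the simplex by sampling sleep, SB and
  MVPA from truncated normals and closing LPA to 1440 (reject-and-redraw
  when any part would be non-positive), around a population mean
  defaulting to (sleep 443, SB 547, LPA 419, MVPA 31) min/day — the
  magnitudes typical of working-age adults measured by a time-use
  questionnaire;
* questionnaire responses for two occasions are constructed by *inverting*
  the scoring rules, so that scoring them reproduces the latent value
  plus an independent per-occasion measurement error (the test-retest
  error); visual-analogue items are quantised to the instrument's 0.01
  grid, with the residual absorbed into the continuous "other" items;
* device event streams tile each noon-to-noon day with a night-long
  sitting/lying block, interleaved waking bouts (sitting, standing, slow
  and fast stepping), optional naps (extra daytime sitting reported in
  the diary), optional non-wear gaps (carved proportionally from the
  waking bouts so that proportional reallocation is exact in
  expectation), and optional upright bursts just after bedtime that
  exercise the sleep-fusion rules; diaries carry the intended onset and
  wake with configurable jitter.

With every noise source at zero the questionnaire scorer and the device
processor each recover the latent composition exactly, which is the
pipeline's primary self-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from datetime import date as Date
from datetime import datetime, time, timedelta
from typing import Mapping

import numpy as np

from .activpal import ActivityClass, DiaryRecord, EventRecord
from .composition import MINUTES_PER_DAY, TimeUseComposition
from .dabq import DABQResponseSet, quantize_vas

#: behaviours drawn directly; LPA is always the closure remainder
DRAWN = ("sleep", "sb", "mvpa")

PerBehaviour = Mapping[str, float]


def per_behaviour(x: float | PerBehaviour) -> dict[str, float]:
    """Broadcast a scalar to {sleep, sb, mvpa} or validate a mapping."""
    if isinstance(x, Mapping):
        missing = set(DRAWN) - set(x)
        if missing:
            raise ValueError(f"missing behaviours: {sorted(missing)}")
        return {b: float(x[b]) for b in DRAWN}
    return {b: float(x) for b in DRAWN}


DEFAULT_MEAN = TimeUseComposition(sleep=443.0, sb=547.0, lpa=419.0, mvpa=31.0)
#: chosen so observed questionnaire SDs land near (60, 165, 165, 35) min/day
DEFAULT_BETWEEN_SD = {"sleep": 50.0, "sb": 130.0, "mvpa": 25.0}
DEFAULT_RETEST_SD = {"sleep": 40.0, "sb": 100.0, "mvpa": 15.0}
#: device minus latent truth, min/day: the device sees more SB and MVPA
#: (and correspondingly less LPA) than the questionnaire's latent scale
DEFAULT_DEVICE_BIAS = {"sleep": -1.0, "sb": 96.5, "mvpa": 39.1}


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for one simulated cohort."""

    n_participants: int = 126
    population_mean_composition: TimeUseComposition = DEFAULT_MEAN
    between_subject_sd: float | PerBehaviour = field(
        default_factory=lambda: dict(DEFAULT_BETWEEN_SD)
    )
    test_retest_error_sd: float | PerBehaviour = field(
        default_factory=lambda: dict(DEFAULT_RETEST_SD)
    )
    device_error_sd: float | PerBehaviour = 25.0
    device_bias: float | PerBehaviour = field(
        default_factory=lambda: dict(DEFAULT_DEVICE_BIAS)
    )
    nonwear_rate: float = 0.25  # expected hours/day
    nap_probability: float = 0.15  # per day
    nap_minutes: float = 30.0
    diary_jitter_sd: float = 10.0  # min, onset/wake diary error
    onset_burst_probability: float = 0.1  # upright burst shortly after bedtime
    onset_burst_delay_min: float = 10.0
    workday_sb_shift: float = 60.0  # min/day moved LPA -> SB on workdays
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("n_participants must be at least 2")
        for name in ("between_subject_sd", "test_retest_error_sd", "device_error_sd"):
            vals = per_behaviour(getattr(self, name))
            if any(v < 0 for v in vals.values()):
                raise ValueError(f"{name} must be non-negative")
        if not self.population_mean_composition.is_closed():
            raise ValueError("population mean composition must close to 1440")


@dataclass(frozen=True)
class TruthProfile:
    """One participant's latent state, fixed across occasions and days."""

    participant_id: str
    latent_composition: TimeUseComposition
    workdays_per_week: int
    shift_work: bool
    occasion_error_sd: dict[str, float]
    device_bias: dict[str, float]
    seed: int

    def __post_init__(self):
        if not 0 <= self.workdays_per_week <= 7:
            raise ValueError("workdays_per_week must be in [0, 7]")
        if not self.latent_composition.is_closed():
            raise ValueError("latent composition must close to 1440")


def _participant_seed(cohort_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([cohort_seed, index])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@lru_cache(maxsize=64)
def _adjusted_loc(target: float, sd: float) -> float:
    """Normal location whose zero-truncated mean equals ``target``.

    Rejection at zero inflates the mean of a normal draw whenever the
    target is within a few SDs of zero (MVPA especially); shifting the
    location compensates so cohort means match the configured values.
    """
    if sd == 0 or target / sd > 6:
        return target
    from scipy import optimize, stats

    def gap(mu):
        return stats.truncnorm.mean(-mu / sd, np.inf, loc=mu, scale=sd) - target

    return float(optimize.brentq(gap, target - 6 * sd, target + sd))


def _draw_composition(
    rng: np.random.Generator,
    mean: TimeUseComposition,
    sd: dict[str, float],
    max_tries: int = 1000,
) -> TimeUseComposition:
    """Truncated-normal simplex draw: sample three parts, close LPA."""
    locs = {b: _adjusted_loc(getattr(mean, b), sd[b]) for b in DRAWN}
    for _ in range(max_tries):
        parts = {b: rng.normal(locs[b], sd[b]) for b in DRAWN}
        lpa = MINUTES_PER_DAY - sum(parts.values())
        if lpa > 0 and all(v > 0 for v in parts.values()):
            return TimeUseComposition(parts["sleep"], parts["sb"], lpa, parts["mvpa"])
    raise RuntimeError("could not draw a positive composition; SDs too large for the mean")


def generate_cohort(config: CohortConfig) -> list[TruthProfile]:
    """Draw a cohort of latent participant profiles, reproducibly."""
    mean = config.population_mean_composition
    between = per_behaviour(config.between_subject_sd)
    retest = per_behaviour(config.test_retest_error_sd)
    bias = per_behaviour(config.device_bias)
    cohort = []
    for i in range(config.n_participants):
        seed = _participant_seed(config.seed, i)
        rng = np.random.default_rng(seed)
        latent = _draw_composition(rng, mean, between)
        workdays = int(rng.choice([0, 4, 5, 6], p=[0.10, 0.10, 0.70, 0.10]))
        shift = bool(rng.random() < 0.2)
        cohort.append(
            TruthProfile(
                participant_id=f"P{i:04d}",
                latent_composition=latent,
                workdays_per_week=workdays,
                shift_work=shift,
                occasion_error_sd=retest,
                device_bias=bias,
                seed=seed,
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# questionnaire response generation (scoring-rule inversion)


def _noisy_target(
    rng: np.random.Generator,
    latent: TimeUseComposition,
    sd: dict[str, float],
    max_tries: int = 1000,
) -> TimeUseComposition:
    """Latent composition plus independent per-behaviour error, re-closed."""
    if all(v == 0 for v in sd.values()):
        return latent
    for _ in range(max_tries):
        parts = {b: getattr(latent, b) + rng.normal(0, sd[b]) for b in DRAWN}
        lpa = MINUTES_PER_DAY - sum(parts.values())
        if lpa > 0 and all(v > 0 for v in parts.values()):
            return TimeUseComposition(parts["sleep"], parts["sb"], lpa, parts["mvpa"])
    raise RuntimeError("could not draw a positive noisy composition")


def _hhmm(minutes_from_midnight: float) -> str:
    m = int(round(minutes_from_midnight)) % (24 * 60)
    return f"{m // 60:02d}:{m % 60:02d}"


def generate_dabq_responses(
    truth: TruthProfile, occasion: int, config: CohortConfig
) -> DABQResponseSet:
    """Emit questionnaire answers that score to latent + occasion noise.

    Clock-time and VAS items are quantised (whole minutes, 0.01 grid);
    the continuous duration items (WASO, "other" SB/MVPA) absorb the
    quantisation residuals so the scored composition equals the target
    to floating-point precision.
    """
    if occasion not in (1, 2):
        raise ValueError("occasion must be 1 or 2")
    rng = np.random.default_rng([truth.seed, 11, occasion])
    target = _noisy_target(rng, truth.latent_composition, truth.occasion_error_sd)

    # --- sleep: bed/rise clock span, latency, WASO, naps
    nap_days = int(rng.binomial(7, config.nap_probability))
    nap_duration = config.nap_minutes if nap_days else 0.0
    nap_daily = nap_days * nap_duration / 7.0
    latency = float(rng.integers(5, 30))
    waso0 = float(rng.integers(0, 25))
    tib_target = target.sleep - nap_daily + latency + waso0
    tib = float(math.ceil(max(tib_target, latency + waso0 + 1)))
    waso = tib + nap_daily - latency - target.sleep  # absorbs ceil residual
    bed_minutes = 23 * 60 + float(rng.integers(-45, 45))
    bed_time = _hhmm(bed_minutes)
    rise_time = _hhmm(bed_minutes + tib)

    # --- SB: occupational VAS share, commute VAS, remainder into "other"
    w = truth.workdays_per_week
    span = float(rng.integers(420, 560)) if w else 480.0
    if w:
        occ_target = min(0.55 * target.sb, span * w / 7.0)
        occ_vas = quantize_vas(occ_target / (span * w / 7.0))
    else:
        occ_vas = 0.0
    occ_sb = span * occ_vas * w / 7.0
    commute_duration = float(rng.integers(10, 60)) if w else 0.0
    rem = max(target.sb - occ_sb, 0.0)
    commute_vas = quantize_vas(min(rem / commute_duration, 1.0)) if commute_duration else 0.0
    commute_sb = commute_duration * commute_vas
    other_sb = max(target.sb - occ_sb - commute_sb, 0.0)

    # --- MVPA: occupational gated by flag, commute daily, remainder "other"
    occ_mvpa_target = min(0.4 * target.mvpa, span) if w else 0.0
    occ_flag = occ_mvpa_target > 0
    occ_days = min(w, 3) if occ_flag else 0
    occ_duration = min(occ_mvpa_target * 7.0 / occ_days, span) if occ_days else 0.0
    occ_mvpa = occ_days * occ_duration / 7.0
    rem_m = max(target.mvpa - occ_mvpa, 0.0)
    commute_mvpa = min(5.0, rem_m) if w else 0.0
    other_m = max(rem_m - commute_mvpa, 0.0)

    arrival = 8 * 60.0
    return DABQResponseSet(
        participant_id=truth.participant_id,
        occasion=occasion,
        bed_time=bed_time,
        rise_time=rise_time,
        sleep_latency=latency,
        waso=waso,
        nap_days=nap_days,
        nap_duration=nap_duration,
        workdays=w,
        work_arrival=_hhmm(arrival),
        work_departure=_hhmm(arrival + span),
        occupational_sb_vas=occ_vas,
        occupational_mvpa_flag=occ_flag,
        occupational_mvpa_days=occ_days,
        occupational_mvpa_duration=occ_duration,
        commute_duration=commute_duration,
        commute_sb_vas=commute_vas,
        commute_mvpa_duration=commute_mvpa,
        other_sb_duration=other_sb,
        other_mvpa_days=7,
        other_mvpa_duration=other_m,
    )


# ---------------------------------------------------------------------------
# device event stream generation

#: simulated measurement weeks start on this Monday
DEFAULT_START_DATE = Date(2022, 3, 7)


@dataclass(frozen=True)
class EventStreamResult:
    events: list[EventRecord]
    diaries: dict[Date, DiaryRecord]
    day_truths: dict[Date, TimeUseComposition]


def _day_truth(
    truth: TruthProfile, is_workday: bool, config: CohortConfig
) -> TimeUseComposition:
    """Workday/non-workday split preserving the weekly mean exactly."""
    c = truth.latent_composition
    w = truth.workdays_per_week
    if w in (0, 7) or config.workday_sb_shift == 0:
        return c
    if is_workday:
        delta = config.workday_sb_shift * (7 - w) / 7.0
    else:
        delta = -config.workday_sb_shift * w / 7.0
    delta = max(min(delta, c.lpa - 1.0), 1.0 - c.sb)  # keep both parts positive
    return TimeUseComposition(c.sleep, c.sb + delta, c.lpa - delta, c.mvpa)


def _tile_slot(
    t0: datetime,
    t1: datetime,
    totals_s: dict[str, float],
    start_upright: bool,
    rng: np.random.Generator,
) -> list[EventRecord]:
    """Fill [t0, t1) with alternating bouts matching the class totals exactly.

    ``totals_s`` carries seconds of sitting (``sit``), standing (``stand``),
    slow stepping (``slow``) and fast stepping (``fast``); their sum must
    equal the slot length.
    """
    order = ["stand", "slow", "sit", "fast"] if start_upright else ["sit", "stand", "fast", "slow"]
    caps = {"sit": 2700.0, "stand": 480.0, "slow": 300.0, "fast": 600.0}
    cls = {
        "sit": (ActivityClass.SITTING_LYING, 0.0),
        "stand": (ActivityClass.STANDING, 0.0),
        "slow": (ActivityClass.STEPPING, 70.0),
        "fast": (ActivityClass.STEPPING, 115.0),
    }
    rem = dict(totals_s)
    events = []
    cursor = t0
    k = 0
    while (t1 - cursor).total_seconds() > 1e-9:
        name = order[k % len(order)]
        k += 1
        if rem[name] <= 1e-9:
            if all(v <= 1e-9 for v in rem.values()):
                break
            continue
        dur = min(rem[name], caps[name], (t1 - cursor).total_seconds())
        ac, cad = cls[name]
        events.append(EventRecord(cursor, dur, ac, cad))
        rem[name] -= dur
        cursor += timedelta(seconds=dur)
    return events


def _apply_bias(comp: TimeUseComposition, bias: dict[str, float]) -> TimeUseComposition:
    """Shift sleep/SB/MVPA by the device bias, compensating through LPA.

    Participants whose latent LPA is too small to absorb the full bias get
    it shrunk proportionally (a device cannot report negative time), so
    the *population-mean* bias is slightly attenuated at extreme margins.
    """
    floors = {b: min(5.0, getattr(comp, b)) for b in DRAWN}
    lpa_floor = min(5.0, comp.lpa)
    f = 1.0
    for _ in range(60):
        parts = {b: getattr(comp, b) + f * bias[b] for b in DRAWN}
        lpa = MINUTES_PER_DAY - sum(parts.values())
        if lpa >= lpa_floor and all(parts[b] >= floors[b] for b in DRAWN):
            return TimeUseComposition(parts["sleep"], parts["sb"], lpa, parts["mvpa"])
        f *= 0.9
    return comp


def generate_event_stream(
    truth: TruthProfile,
    config: CohortConfig,
    n_days: int = 7,
    start_date: Date = DEFAULT_START_DATE,
) -> EventStreamResult:
    """Simulate a measurement week of device events plus sleep diaries.

    Each noon-to-noon day holds one night sitting/lying block and waking
    bouts whose class totals equal the day's (device-biased, noisy)
    composition; the per-day *latent* truth is returned for testing.
    """
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    rng = np.random.default_rng([truth.seed, 77])
    bias = truth.device_bias
    dev_sd = per_behaviour(config.device_error_sd)
    events: list[EventRecord] = []
    diaries: dict[Date, DiaryRecord] = {}
    day_truths: dict[Date, TimeUseComposition] = {}

    for d in range(n_days):
        day = start_date + timedelta(days=d)
        is_workday = day.weekday() < truth.workdays_per_week  # Mon..Fri style
        truth_day = _day_truth(truth, is_workday, config)
        day_truths[day] = truth_day

        biased = _apply_bias(truth_day, bias)
        measured = _noisy_target(rng, biased, dev_sd)

        nap = config.nap_minutes if rng.random() < config.nap_probability else 0.0
        night_min = measured.sleep - nap
        if night_min < 60:
            nap, night_min = 0.0, measured.sleep

        noon = datetime.combine(day, time(12, 0))
        onset = noon + timedelta(minutes=660 + float(rng.normal(0, 15)))
        wake = onset + timedelta(minutes=night_min)

        # diary with jitter
        jit = config.diary_jitter_sd
        diary_onset = onset + timedelta(minutes=float(rng.normal(0, jit)))
        diary_wake = wake + timedelta(minutes=float(rng.normal(0, jit)))
        diaries[day] = DiaryRecord(day, diary_onset, diary_wake, nap)

        # optional upright burst splitting the start of the night
        burst_events: list[EventRecord] = []
        night_start = onset
        if rng.random() < config.onset_burst_probability:
            b0 = onset + timedelta(minutes=config.onset_burst_delay_min)
            burst_events = [
                EventRecord(night_start, (b0 - night_start).total_seconds(), ActivityClass.SITTING_LYING),
                EventRecord(b0, 60.0, ActivityClass.STANDING),
                EventRecord(b0 + timedelta(seconds=60), 60.0, ActivityClass.STEPPING, 80.0),
            ]
            night_start = b0 + timedelta(seconds=120)
        burst_events.append(
            EventRecord(night_start, (wake - night_start).total_seconds(), ActivityClass.SITTING_LYING)
        )

        # waking slots and their class totals
        next_noon = noon + timedelta(days=1)
        w1 = (onset - noon).total_seconds()
        w2 = (next_noon - wake).total_seconds()
        w_avail = w1 + w2

        gap_s = 0.0
        if config.nonwear_rate > 0:
            gap_s = min(float(rng.exponential(config.nonwear_rate * 3600.0)), w1 - 3600.0)
            if gap_s < 300.0:
                gap_s = 0.0
        shrink = (w_avail - gap_s) / w_avail

        sit_total = (measured.sb + nap) * 60.0 * shrink
        lpa_total = measured.lpa * 60.0 * shrink
        fast_total = measured.mvpa * 60.0 * shrink
        slow_total = min(0.25 * lpa_total, 0.3 * lpa_total)
        stand_total = lpa_total - slow_total

        gap_start = noon + timedelta(hours=3)
        slots: list[tuple[datetime, datetime, bool]] = []
        if gap_s > 0:
            slots.append((noon, gap_start, False))
            slots.append((gap_start + timedelta(seconds=gap_s), onset, False))
        else:
            slots.append((noon, onset, False))
        slots.append((wake, next_noon, True))

        total_slot_s = sum((b - a).total_seconds() for a, b, _ in slots)
        for a, b, upright_first in slots:
            frac = (b - a).total_seconds() / total_slot_s
            tot = {
                "sit": sit_total * frac,
                "stand": stand_total * frac,
                "slow": slow_total * frac,
                "fast": fast_total * frac,
            }
            # closure within the slot: absorb float drift into sitting
            drift = (b - a).total_seconds() - sum(tot.values())
            tot["sit"] += drift
            events.extend(_tile_slot(a, b, tot, upright_first, rng))

        events.extend(burst_events)

    events.sort(key=lambda e: e.start)
    return EventStreamResult(events, diaries, day_truths)


def error_sd_for_icc(between_sd: float, icc: float) -> float:
    """Occasion-error SD giving a target true ICC for a known between-SD.

    ICC = s_b^2 / (s_b^2 + s_e^2)  =>  s_e = s_b * sqrt((1 - ICC)/ICC).
    """
    if not 0 < icc <= 1:
        raise ValueError("icc must be in (0, 1]")
    return between_sd * math.sqrt((1 - icc) / icc)
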