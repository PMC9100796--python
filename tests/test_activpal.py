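"""Device processing: hand-traced sleep fusion, classification, non-wear.

The fusion fixtures encode the decision rules verbatim: a 20-min
post-bedtime window decides between diary and device for sleep onset; the
first upright burst after more than an hour of sitting/lying decides the
offset.  A sampling-based brute-force scanner re-derives the same
decisions on random streams.
"""

from __future__ import annotations

from dataclasses import replace
from datetime import date, datetime, timedelta

import numpy as np
import pytest

from conftest import BASE_DATE, build_events, ts
from timeuse24.activpal import (
    ActivityClass,
    DailyBehaviourSummary,
    DiaryRecord,
    EventRecord,
    FusionSource,
    ProcessingConfig,
    SleepWindow,
    account_nonwear,
    adjust_naps,
    average_week,
    classify_waking,
    day_window,
    detect_time_in_bed,
    fuse_sleep_onset,
    fuse_sleep_offset,
    reallocate_nonwear,
    summarize_day,
)

CFG = ProcessingConfig()
WINDOW = day_window(BASE_DATE)


def diary(onset="23:00", wake="07:00", nap=0.0):
    return DiaryRecord(BASE_DATE, ts(onset), ts(wake), nap)


class TestTimeInBed:
    def test_single_interruption_within_budget(self):
        events = build_events(
            [("22:40", "03:00", "sit"), ("03:00", "03:10", "stand"), ("03:10", "06:50", "sit")]
        )
        w = detect_time_in_bed(events, WINDOW, CFG)
        assert (w.onset, w.offset) == (ts("22:40"), ts("06:50"))

    def test_budget_exceeded_picks_longer_block(self):
        # two 10-min interruptions (20 total): only one may be merged;
        # 01:10-07:00 (350 min incl. its gap) beats 22:00-03:00 (300 min)
        events = build_events(
            [
                ("22:00", "01:00", "sit"),
                ("01:00", "01:10", "stand"),
                ("01:10", "03:00", "sit"),
                ("03:00", "03:10", "stand"),
                ("03:10", "07:00", "sit"),
            ]
        )
        w = detect_time_in_bed(events, WINDOW, CFG)
        assert (w.onset, w.offset) == (ts("01:10"), ts("07:00"))

    def test_uninterrupted_block_verbatim(self):
        events = build_events([("23:00", "07:00", "sit")])
        w = detect_time_in_bed(events, WINDOW, CFG)
        assert (w.onset, w.offset) == (ts("23:00"), ts("07:00"))

    def test_no_sitting_lying(self):
        events = build_events([("13:00", "14:00", "stand")])
        assert detect_time_in_bed(events, WINDOW, CFG) is None


NIGHT = SleepWindow(BASE_DATE, ts("23:00"), ts("07:00"))


class TestOnsetFusion:
    def test_quiet_window_keeps_diary(self):
        events = build_events([("22:00", "23:00", "sit"), ("23:00", "07:00", "sit")])
        t, src = fuse_sleep_onset(diary(), events, NIGHT, CFG)
        assert (t, src) == (ts("23:00"), FusionSource.DIARY)

    def test_burst_in_window_moves_to_first_sit_after(self):
        events = build_events(
            [
                ("22:00", "23:05", "sit"),
                ("23:05", "23:08", "stand"),
                ("23:08", "23:12", "step"),
                ("23:12", "07:00", "sit"),
            ]
        )
        t, src = fuse_sleep_onset(diary(), events, NIGHT, CFG)
        assert (t, src) == (ts("23:12"), FusionSource.EVENT)

    def test_burst_outside_window_keeps_diary(self):
        events = build_events(
            [
                ("22:00", "23:25", "sit"),
                ("23:25", "23:30", "stand"),
                ("23:30", "07:00", "sit"),
            ]
        )
        t, src = fuse_sleep_onset(diary(), events, NIGHT, CFG)
        assert (t, src) == (ts("23:00"), FusionSource.DIARY)

    def test_missing_diary_falls_back_to_candidate(self):
        events = build_events([("23:00", "07:00", "sit")])
        t, src = fuse_sleep_onset(None, events, NIGHT, CFG)
        assert (t, src) == (NIGHT.onset, FusionSource.EVENT)

    def test_sub_burst_interruption_ignored(self):
        # 30 s standing within the window is below the 60-s burst floor
        events = build_events([("22:00", "23:10", "sit"), ("23:11", "07:00", "sit")]) + [
            EventRecord(ts("23:10"), 30.0, ActivityClass.STANDING),
        ]
        events.sort(key=lambda e: e.start)
        t, src = fuse_sleep_onset(diary(), events, NIGHT, CFG)
        assert (t, src) == (ts("23:00"), FusionSource.DIARY)


class TestOffsetFusion:
    def _morning(self, diary_wake):
        events = build_events(
            [
                ("23:00", "06:40", "sit"),
                ("06:40", "06:50", "stand"),
                ("06:50", "07:30", "sit"),
            ]
        )
        return fuse_sleep_offset(diary(wake=diary_wake), events, NIGHT, ts("23:00"), CFG)

    def test_diary_before_burst_wins(self):
        t, src = self._morning("06:30")
        assert (t, src) == (ts("06:30"), FusionSource.DIARY)

    def test_diary_after_burst_loses_to_event(self):
        t, src = self._morning("07:00")
        assert (t, src) == (ts("06:40"), FusionSource.EVENT)

    def test_no_burst_all_morning_keeps_diary(self):
        events = build_events([("23:00", "09:00", "sit")])
        t, src = fuse_sleep_offset(diary(wake="07:00"), events, NIGHT, ts("23:00"), CFG)
        assert (t, src) == (ts("07:00"), FusionSource.DIARY)

    def test_missing_diary_falls_back_to_candidate(self):
        events = build_events([("23:00", "07:00", "sit")])
        t, src = fuse_sleep_offset(None, events, NIGHT, ts("23:00"), CFG)
        assert (t, src) == (NIGHT.offset, FusionSource.EVENT)

    def test_burst_after_short_sitting_does_not_qualify(self):
        # the first burst follows only 30 min of sitting/lying; the
        # qualifying burst comes after the long block, and the diary
        # precedes it
        events = build_events(
            [
                ("23:00", "06:40", "sit"),
                ("06:40", "06:50", "stand"),
                ("06:50", "07:20", "sit"),  # 30 min < 1 h: burst at 07:20 not reached first
                ("07:20", "07:30", "stand"),
            ]
        )
        t, src = fuse_sleep_offset(diary(wake="06:35"), events, NIGHT, ts("23:00"), CFG)
        assert (t, src) == (ts("06:35"), FusionSource.DIARY)


class TestClassification:
    def test_hand_tiled_day(self):
        # 480 sleep + 600 waking sitting + 60 fast stepping + 300 standing
        events = build_events(
            [("12:00", "18:00", "sit"), ("18:00", "23:00", "stand")]  # 360 sit + 300 stand
        )
        events += build_events([("23:00", "07:00", "sit")])  # night
        events += build_events([("07:00", "11:00", "sit")])  # 240 sit
        events += [EventRecord(ts("11:00"), 3600.0, ActivityClass.STEPPING, 115.0)]
        sw = SleepWindow(BASE_DATE, ts("23:00"), ts("07:00"))
        mins = classify_waking(events, sw, WINDOW, CFG)
        assert mins == {"sb": 600.0, "lpa": 300.0, "mvpa": 60.0}

    @pytest.mark.parametrize("cadence,bucket", [(115.0, "mvpa"), (80.0, "lpa")])
    def test_cadence_threshold(self, cadence, bucket):
        events = [EventRecord(ts("14:00"), 600.0, ActivityClass.STEPPING, cadence)]
        mins = classify_waking(events, NIGHT, WINDOW, CFG)
        assert mins[bucket] == 10.0

    def test_event_split_at_sleep_boundary(self):
        events = build_events([("22:30", "23:30", "sit")])
        mins = classify_waking(events, NIGHT, WINDOW, CFG)
        assert mins["sb"] == 30.0  # only 22:30-23:00 is waking


class TestNonwear:
    def test_fully_tiled_day_is_valid(self):
        events = [EventRecord(WINDOW[0], 86400.0, ActivityClass.SITTING_LYING)]
        nonwear, wear, valid = account_nonwear(events, WINDOW, CFG)
        assert (nonwear, wear, valid) == (0.0, 1440.0, True)

    @pytest.mark.parametrize("gap_h,expect_valid", [(5.0, False), (3.5, True)])
    def test_gap_thresholds(self, gap_h, expect_valid):
        gap_s = gap_h * 3600
        events = [
            EventRecord(WINDOW[0], 3600.0, ActivityClass.SITTING_LYING),
            EventRecord(
                WINDOW[0] + timedelta(seconds=3600 + gap_s),
                86400.0 - 3600.0 - gap_s,
                ActivityClass.SITTING_LYING,
            ),
        ]
        nonwear, wear, valid = account_nonwear(events, WINDOW, CFG)
        assert nonwear == pytest.approx(gap_h * 60)
        assert valid is expect_valid


def make_summary(sleep=480.0, sb=480.0, lpa=300.0, mvpa=60.0, nonwear=120.0, **kw):
    defaults = dict(date=BASE_DATE, wear=1440.0 - nonwear, valid=True)
    defaults.update(kw)
    return DailyBehaviourSummary(sleep=sleep, sb=sb, lpa=lpa, mvpa=mvpa, nonwear=nonwear, **defaults)


class TestNapsAndReallocation:
    def test_nap_moves_sb_to_sleep(self):
        s = adjust_naps(make_summary(sleep=450.0, sb=600.0), diary(nap=30.0))
        assert (s.sleep, s.sb) == (480.0, 570.0)

    def test_zero_nap_is_identity(self):
        s = make_summary()
        assert adjust_naps(s, diary(nap=0.0)) == s

    def test_nap_overshoot_clamps_and_flags(self):
        s = adjust_naps(make_summary(sleep=480.0, sb=20.0), diary(nap=30.0))
        assert s.sb == 0.0
        assert s.sleep == 500.0
        assert "nap_exceeds_sb" in s.flags

    def test_reallocation_scales_waking_only(self):
        s = reallocate_nonwear(make_summary())
        scale = 960 / 840
        assert s.sleep == 480.0
        assert s.sb == pytest.approx(480 * scale)
        assert s.lpa == pytest.approx(300 * scale)
        assert s.mvpa == pytest.approx(60 * scale)
        assert s.sleep + s.sb + s.lpa + s.mvpa == pytest.approx(1440.0)

    def test_reallocation_identity_without_nonwear(self):
        s = make_summary(nonwear=0.0)
        assert reallocate_nonwear(s) == s

    def test_reallocation_preserves_zeros(self):
        s = reallocate_nonwear(make_summary(mvpa=0.0, lpa=360.0))
        assert s.mvpa == 0.0


class TestWeeklyAverage:
    def _week(self, sleeps, valid_days=None):
        out = []
        for i, sl in enumerate(sleeps):
            out.append(
                make_summary(
                    sleep=sl, sb=1440 - sl - 360.0, lpa=300.0, mvpa=60.0, nonwear=0.0,
                    date=BASE_DATE + timedelta(days=i),
                    valid=True if valid_days is None else (i < valid_days),
                )
            )
        return out

    def test_mean_of_constant_days(self):
        comp = average_week(self._week([460.0] * 7))
        assert comp.sleep == 460.0 and comp.valid

    def test_hand_mean(self):
        comp = average_week(self._week([420.0, 440, 460, 480, 500]))
        assert comp.sleep == pytest.approx(460.0)
        assert comp.is_closed()

    def test_four_valid_days_excluded(self):
        comp = average_week(self._week([460.0] * 7, valid_days=4))
        assert not comp.valid

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            average_week([])


# ---------------------------------------------------------------------------
# brute-force fusion oracle on random streams


def _upright_seconds(events, t0, t1):
    """Sampled (1-s bins) upright occupancy in [t0, t1)."""
    total = 0
    for e in events:
        if not e.upright:
            continue
        s = max(e.start, t0)
        f = min(e.end, t1)
        if f > s:
            step = s
            while step < f:
                total += 1
                step += timedelta(seconds=1)
    return total


def _oracle_anchors(events, cfg):
    anchors = []
    for e in events:
        if not e.upright:
            continue
        if _upright_seconds(events, e.start, e.start + timedelta(seconds=cfg.burst_window_s)) >= cfg.burst_upright_s:
            if not anchors or (e.start - anchors[-1]).total_seconds() > cfg.burst_window_s:
                anchors.append(e.start)
    return anchors


def _oracle_onset(d, events, candidate, cfg):
    t0 = d.intended_onset
    t1 = t0 + timedelta(minutes=cfg.onset_search_min)
    from timeuse24.activpal import _clip_events

    clipped = _clip_events(events, t0, t1 + timedelta(seconds=cfg.burst_window_s))
    inwin = [a for a in _oracle_anchors(clipped, cfg) if t0 <= a < t1]
    if not inwin:
        return t0
    sits = [e.start for e in events if not e.upright and e.start >= inwin[-1]]
    return sits[0] if sits else candidate.onset


def _oracle_offset(d, events, onset, candidate, cfg):
    from timeuse24.activpal import _clip_events, _sit_lie_runs

    tail = [e for e in events if e.end > onset]
    runs = _sit_lie_runs(_clip_events(tail, onset, tail[-1].end)) if tail else []
    for a, b in runs:
        if (b - a).total_seconds() > cfg.offset_prior_sitting_min * 60:
            after = [e for e in tail if e.end > b]
            anchors = [t for t in _oracle_anchors(after, cfg) if t >= b]
            if anchors:
                if d.wake_time <= anchors[0]:
                    return d.wake_time
                ends = [e.end for e in tail if not e.upright and e.end <= anchors[0]]
                return ends[-1] if ends else anchors[0]
    return d.wake_time


@pytest.mark.parametrize("trial", range(30))
def test_fusion_matches_sampling_oracle(trial):
    """Fused onset/offset equal a second-sampled literal rule application."""
    rng = np.random.default_rng(1000 + trial)
    cursor = ts("20:00")
    events = []
    # evening activity, a night block, and a morning with random bouts
    for _ in range(int(rng.integers(3, 10))):
        cls = rng.choice(["sit", "stand", "step"], p=[0.5, 0.3, 0.2])
        dur = int(rng.integers(60, 1800))
        events.append(
            EventRecord(
                cursor, float(dur),
                {"sit": ActivityClass.SITTING_LYING, "stand": ActivityClass.STANDING,
                 "step": ActivityClass.STEPPING}[cls],
                80.0 if cls == "step" else 0.0,
            )
        )
        cursor += timedelta(seconds=dur)
    night_len = int(rng.integers(4 * 3600, 8 * 3600))
    events.append(EventRecord(cursor, float(night_len), ActivityClass.SITTING_LYING))
    cursor += timedelta(seconds=night_len)
    for _ in range(int(rng.integers(3, 12))):
        cls = rng.choice(["sit", "stand", "step"], p=[0.4, 0.35, 0.25])
        dur = int(rng.integers(30, 2400))
        events.append(
            EventRecord(
                cursor, float(dur),
                {"sit": ActivityClass.SITTING_LYING, "stand": ActivityClass.STANDING,
                 "step": ActivityClass.STEPPING}[cls],
                80.0 if cls == "step" else 0.0,
            )
        )
        cursor += timedelta(seconds=dur)

    candidate = detect_time_in_bed(events, (ts("12:00"), ts("12:00", 1)), CFG)
    if candidate is None:
        return
    d = DiaryRecord(
        BASE_DATE,
        candidate.onset + timedelta(minutes=float(rng.integers(-25, 26))),
        candidate.offset + timedelta(minutes=float(rng.integers(-25, 26))),
    )
    onset, _ = fuse_sleep_onset(d, events, candidate, CFG)
    assert onset == _oracle_onset(d, events, candidate, CFG)
    offset, _ = fuse_sleep_offset(d, events, candidate, onset, CFG)
    assert offset == _oracle_offset(d, events, onset, candidate, CFG)


class TestSummarizeDay:
    def test_noise_free_hand_built_day(self):
        events = [EventRecord(WINDOW[0], 6 * 3600.0, ActivityClass.SITTING_LYING)]  # 12-18 sit
        events += [EventRecord(ts("18:00"), 5 * 3600.0, ActivityClass.STANDING)]  # 18-23 stand
        events += [EventRecord(ts("23:00"), 8 * 3600.0, ActivityClass.SITTING_LYING)]  # night
        events += [EventRecord(ts("07:00"), 3600.0, ActivityClass.STANDING)]  # 07-08
        events += [EventRecord(ts("08:00"), 3 * 3600.0, ActivityClass.SITTING_LYING)]  # 08-11
        events += [EventRecord(ts("11:00"), 3600.0, ActivityClass.STEPPING, 120.0)]  # 11-12
        s = summarize_day(events, diary(), BASE_DATE, CFG)
        assert s.valid
        assert s.sleep == pytest.approx(480.0)
        assert s.sb == pytest.approx(540.0)
        assert s.lpa == pytest.approx(360.0)
        assert s.mvpa == pytest.approx(60.0)
        assert s.sleep + s.sb + s.lpa + s.mvpa == pytest.approx(1440.0)

    def test_closure_with_nonwear_reallocated(self):
        events = [EventRecord(WINDOW[0], 4 * 3600.0, ActivityClass.SITTING_LYING)]
        # 2-h gap 16:00-18:00
        events += [EventRecord(ts("18:00"), 5 * 3600.0, ActivityClass.STANDING)]
        events += [EventRecord(ts("23:00"), 8 * 3600.0, ActivityClass.SITTING_LYING)]
        events += [EventRecord(ts("07:00"), 5 * 3600.0, ActivityClass.STANDING)]
        s = summarize_day(events, diary(), BASE_DATE, CFG)
        assert s.valid  # 22 h wear
        assert s.nonwear == 0.0  # reallocated
        assert s.sleep + s.sb + s.lpa + s.mvpa == pytest.approx(1440.0)
        assert s.sleep == pytest.approx(480.0)  # sleep untouched by reallocation
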