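"""Circadian BP parameter extraction: split, stats, loads, dipping, w-BPV,
postprandial hypotension and morning hypotensive episodes."""

from __future__ import annotations

import random
from dataclasses import replace
from datetime import datetime, time, timedelta

import numpy as np
import pytest
from hypothesis import given, strategies as st

from abpmaf.features import (
    FeatureConfig,
    awakening_hypotension,
    bp_load,
    extract_features,
    hypotensive_episodes,
    period_stats,
    postprandial_hypotension,
    reverse_dipping,
    split_day_night,
    weighted_bpv,
)
from abpmaf.io import ABPMRecording, BPReading, DiaryEvent, EventKind, ValidationError

from conftest import START, flat_recording, make_recording, standard_diary


def _readings(values, start=START, cadence=15):
    return [
        BPReading(start + i * timedelta(minutes=cadence), float(v), float(v) - 45.0)
        for i, v in enumerate(values)
    ]


class TestSplitDayNight:
    def test_hand_counted_partition(self, recording_96):
        split = split_day_night(recording_96)
        assert len(split.day_readings) == 64  # [07:00, 23:00) at 15-min cadence
        assert len(split.night_readings) == 32  # [23:00, 07:00)
        assert split.day_hours == pytest.approx(16.0)
        # night interval clipped at the last reading (06:45)
        assert split.night_hours == pytest.approx(7.75)

    def test_fallback_matches_explicit_diary(self, recording_96):
        explicit = split_day_night(recording_96)
        wake_only = [e for e in recording_96.diary if e.kind == EventKind.AWAKENING]
        bare = ABPMRecording("p1", recording_96.readings, wake_only)
        fallback = split_day_night(
            bare, FeatureConfig(day_night_fallback=(time(7), time(23)))
        )
        assert fallback.used_fallback
        assert fallback.day_readings == explicit.day_readings
        assert fallback.night_readings == explicit.night_readings

    def test_fallback_disabled_is_error(self, recording_96):
        bare = ABPMRecording(
            "p1",
            recording_96.readings,
            [e for e in recording_96.diary if e.kind == EventKind.AWAKENING],
        )
        with pytest.raises(ValidationError, match="fallback disabled"):
            split_day_night(bare, FeatureConfig(day_night_fallback=None))

    def test_empty_night_is_error(self, recording_96):
        # sleep onset after the final reading leaves the night empty
        late = datetime(2021, 3, 2, 6, 50)
        diary = [
            DiaryEvent(START, EventKind.AWAKENING),
            DiaryEvent(late, EventKind.SLEEP_ONSET),
        ]
        with pytest.raises(ValidationError, match="empty"):
            split_day_night(ABPMRecording("p1", recording_96.readings[:-1], diary))


class TestPeriodStats:
    def test_hand_computed_mean_sd(self):
        mean, sd = period_stats(_readings([110, 120, 130]), "sbp")
        assert (mean, sd) == (120.0, pytest.approx(10.0))

    def test_constant_series(self):
        assert period_stats(_readings([120, 120, 120]), "sbp") == (120.0, 0.0)

    def test_single_reading_policy(self):
        with pytest.raises(ValidationError):
            period_stats(_readings([120]), "sbp")
        cfg = FeatureConfig(sd_single_reading_is_error=False)
        assert period_stats(_readings([120]), "sbp", cfg) == (120.0, 0.0)

    def test_empty_is_error(self):
        with pytest.raises(ValidationError):
            period_stats([], "sbp")


class TestBPLoad:
    def test_hand_counted_day_load(self):
        from abpmaf.features import DayNightSplit

        split = DayNightSplit(_readings([130, 140, 136]), _readings([100, 100]), 16, 8)
        assert bp_load(split, "day", "sbp") == pytest.approx(200 / 3)

    def test_boundary_at_threshold_counts(self):
        from abpmaf.features import DayNightSplit

        split = DayNightSplit(_readings([135, 135]), _readings([120, 120]), 16, 8)
        assert bp_load(split, "day", "sbp") == 100.0
        assert bp_load(split, "night", "sbp") == 100.0

    def test_all_below_threshold(self):
        from abpmaf.features import DayNightSplit

        split = DayNightSplit(_readings([134, 120]), _readings([119]), 16, 8)
        assert bp_load(split, "day", "sbp") == 0.0
        assert bp_load(split, "night", "sbp") == 0.0


class TestDippingAndVariability:
    def test_reverse_dipping_group_mean_cases(self):
        from abpmaf.features import DayNightSplit

        # AF-positive-like profile: night above day
        assert reverse_dipping(DayNightSplit(_readings([118]), _readings([122]), 16, 8))
        # AF-negative-like profile: normal dip
        assert not reverse_dipping(DayNightSplit(_readings([122]), _readings([109]), 16, 8))
        # boundary: equal means count as reverse dipping (difference <= 0)
        assert reverse_dipping(DayNightSplit(_readings([120]), _readings([120]), 16, 8))

    def test_weighted_bpv_hand_computed(self):
        from abpmaf.features import DayNightSplit

        day = _readings([110, 120, 130])  # sd 10
        night = _readings([106, 120, 134])  # sd 14
        value, increased = weighted_bpv(DayNightSplit(day, night, 16.0, 8.0))
        assert value == pytest.approx((10 * 16 + 14 * 8) / 24)  # 11.33
        assert increased

    def test_weighted_bpv_symmetry_and_zero(self):
        from abpmaf.features import DayNightSplit

        day = _readings([108, 120, 132])  # sd 12
        night = _readings([108, 120, 132])
        v1 = weighted_bpv(DayNightSplit(day, night, 16.0, 8.0))
        v2 = weighted_bpv(DayNightSplit(day, night, 10.0, 14.0))
        assert v1.value == pytest.approx(12.0)
        assert v2.value == pytest.approx(12.0)
        flatd = _readings([120, 120])
        v, inc = weighted_bpv(DayNightSplit(flatd, flatd, 16.0, 8.0))
        assert (v, inc) == (0.0, False)

    @given(st.integers(0, 2**31 - 1))
    def test_wbpv_between_period_sds(self, seed):
        from abpmaf.features import DayNightSplit

        rng = np.random.default_rng(seed)
        day = _readings(rng.normal(120, rng.uniform(1, 15), 10).round(1))
        night = _readings(rng.normal(110, rng.uniform(1, 15), 10).round(1))
        _, sd_d = period_stats(day, "sbp")
        _, sd_n = period_stats(night, "sbp")
        v = weighted_bpv(DayNightSplit(day, night, 16.0, 7.75)).value
        assert min(sd_d, sd_n) - 1e-9 <= v <= max(sd_d, sd_n) + 1e-9


class TestPostprandialHypotension:
    def _with_post_meal_min(self, post_min):
        # meal at 08:00; last three readings strictly before it (07:15, 07:30,
        # 07:45) are 128, 132, 130 -> reference mean 130; trough at 08:15,
        # inside the (08:00, 10:00] window
        series = [130.0, 128.0, 132.0, 130.0, 132.0, post_min] + [125.0] * 90
        return make_recording(series[:96])

    def test_hand_computed_drop(self):
        pph, drops = postprandial_hypotension(self._with_post_meal_min(108.0))
        assert pph and max(drops) == pytest.approx(22.0)

    def test_boundary_drop_of_exactly_20(self):
        pph, drops = postprandial_hypotension(self._with_post_meal_min(110.0))
        assert pph and max(drops) == pytest.approx(20.0)

    def test_no_drop(self):
        rec = make_recording([130.0] * 96)
        pph, drops = postprandial_hypotension(rec)
        assert not pph and all(d <= 0 for d in drops)

    def test_meal_without_three_prior_readings_skipped(self):
        # meal 15 min after recording start: only 1 prior reading
        diary = standard_diary()
        early = [DiaryEvent(START + timedelta(minutes=15), EventKind.MEAL), *diary]
        rec = make_recording([130.0] * 96, diary=early)
        pph, drops = postprandial_hypotension(rec)
        assert len(drops) == 3  # the early meal was skipped, the 3 diary meals analysed

    def test_zero_analysable_meals_error(self):
        diary = [
            DiaryEvent(START, EventKind.AWAKENING),
            DiaryEvent(START + timedelta(minutes=15), EventKind.MEAL),
        ]
        rec = make_recording([130.0] * 96, diary=diary)
        with pytest.raises(ValidationError, match="no analysable meal"):
            postprandial_hypotension(rec)


class TestHypotensiveEpisodes:
    def _morning(self, window_values, fill=125.0):
        # window [07:00 awakening, 13:00 lunch) = first 24 slots
        values = list(window_values) + [fill] * (96 - len(window_values))
        return make_recording(values)

    def test_hand_counted_episodes(self):
        rec = self._morning([100.0, 110.0, 104.0])
        n, times = hypotensive_episodes(rec, mean_sbp_24h=120.0)
        assert n == 2
        assert times == [rec.readings[0].timestamp, rec.readings[2].timestamp]

    def test_boundary_exactly_15_below_counted(self):
        rec = self._morning([105.0])
        n, _ = hypotensive_episodes(rec, 120.0)
        assert n == 1

    def test_no_episodes(self):
        rec = self._morning([120.0, 125.0])
        assert hypotensive_episodes(rec, 120.0)[0] == 0

    def test_lunch_fallback_window(self):
        diary = [e for e in standard_diary() if e.kind != EventKind.MEAL]
        diary.append(DiaryEvent(START + timedelta(hours=1), EventKind.MEAL))  # 08:00 only
        # dip at 11:30 (inside awakening+5h) and at 12:30 (outside)
        values = [125.0] * 96
        values[18] = 100.0
        values[22] = 100.0
        rec = make_recording(values, diary=diary)
        n, _ = hypotensive_episodes(rec, 120.0, FeatureConfig(lunch_fallback_hours=5.0))
        assert n == 1
        with pytest.raises(ValidationError, match="fallback disabled"):
            hypotensive_episodes(rec, 120.0, FeatureConfig(lunch_fallback_hours=None))

    def test_awakening_hypotension_window(self):
        aw = START
        assert awakening_hypotension([aw + timedelta(minutes=30)], aw)
        assert awakening_hypotension([aw + timedelta(minutes=90)], aw)
        assert not awakening_hypotension([aw + timedelta(minutes=91)], aw)
        assert not awakening_hypotension([], aw)


class TestExtractFeatures:
    def test_flat_recording(self):
        fv = extract_features(flat_recording())
        assert fv.sd_sbp_24h == fv.sd_sbp_day == fv.sd_sbp_night == 0.0
        assert fv.load_sbp_day == fv.load_dbp_day == 0.0
        assert fv.load_sbp_night == fv.load_dbp_night == 0.0
        assert fv.w_bpv == 0.0
        assert not fv.pph and not fv.hypo_aw and fv.n_hypo_ep == 0
        # equal day and night means sit on the reverse-dipping boundary
        assert fv.reverse_dipping

    def test_engineered_dips_and_reverse_dipping(self):
        values = [118.0] * 64 + [125.0] * 32  # night above day
        for i in (2, 9, 17):  # three morning dips
            values[i] = 75.0
        fv = extract_features(make_recording(values))
        assert fv.n_hypo_ep == 3
        assert fv.hypo_aw  # dip at slot 2 = 30 min after awakening
        assert fv.reverse_dipping

    def test_reorder_invariance(self):
        values = [118.0 + (i * 7) % 13 for i in range(96)]
        rec = make_recording(values)
        shuffled = ABPMRecording(
            rec.patient_id,
            random.Random(3).sample(rec.readings, len(rec.readings)),
            rec.diary,
        ).sorted()
        assert extract_features(rec) == extract_features(shuffled)

    @given(st.integers(-20, 40), st.integers(0, 2**31 - 1))
    def test_shift_invariance(self, c, seed):
        """Adding +c to every SBP shifts means by c and leaves SDs, w-BPV,
        dipping status and the episode count unchanged."""
        rng = np.random.default_rng(seed)
        values = rng.normal(125, 8, 96).round()
        rec = make_recording(values, dbp_offset=45.0)
        shifted = make_recording(values + c, dbp_offset=45.0)
        a, b = extract_features(rec), extract_features(shifted)
        assert b.mean_sbp_24h == pytest.approx(a.mean_sbp_24h + c)
        assert b.mean_sbp_night == pytest.approx(a.mean_sbp_night + c)
        assert b.sd_sbp_24h == pytest.approx(a.sd_sbp_24h)
        assert b.w_bpv == pytest.approx(a.w_bpv)
        assert b.reverse_dipping == a.reverse_dipping
        assert b.n_hypo_ep == a.n_hypo_ep

    def test_hypo_aw_implies_episode(self):
        # invariant holds on arbitrary generated patients
        from abpmaf.synth import CohortConfig, generate_cohort

        cohort = generate_cohort(CohortConfig(n_patients=30, seed=7))
        for rec in cohort.recordings:
            fv = extract_features(rec)
            assert (not fv.hypo_aw) or fv.n_hypo_ep >= 1
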