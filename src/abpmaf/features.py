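"""ABPM-derived parameters used to screen for autonomic failure.

From one 24-h recording this module derives:

* period (24-h / daytime / night-time) means and SDs of SBP, MBP, DBP,
  where day and night are delimited by the patient's diary (night is the
  half-open interval [sleep onset, next awakening));
* BP loads — the percentage of readings at or above the European Society of
  Hypertension reference values (day 135/85, night 120/70 mmHg);
* reverse dipping — systolic day-night difference <= 0 mmHg;
* weighted blood-pressure variability (w-BPV) — the duration-weighted
  average of day and night systolic SDs, "increased" when > 11 mmHg;
* postprandial hypotension (PPH) — an SBP drop >= 20 mmHg within 120 min
  after any diary meal, against the mean of the last three pre-meal readings;
* morning hypotensive episodes — readings at least 15 mmHg below the 24-h
  mean SBP between awakening and lunch — and awakening hypotension
  (>= 1 such episode within 90 min of awakening).

All interval conventions are half-open [a, b) except where a criterion says
"within", which is read as an inclusive upper bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from datetime import datetime, time, timedelta
from typing import Iterable, Literal, NamedTuple, Optional, Sequence

import numpy as np

from .io import ABPMRecording, BPReading, EventKind, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig",
    "DayNightSplit",
    "FeatureVector",
    "FEATURE_COLUMNS",
    "BINARY_FEATURES",
    "LOAD_THRESHOLDS",
    "WBPV_INCREASED_THRESHOLD",
    "split_day_night",
    "period_stats",
    "bp_load",
    "reverse_dipping",
    "weighted_bpv",
    "postprandial_hypotension",
    "hypotensive_episodes",
    "awakening_hypotension",
    "extract_features",
]

Component = Literal["sbp", "dbp", "mbp"]
Period = Literal["day", "night"]

#: reference values for BP load, mmHg ("exceeding" read as >=)
LOAD_THRESHOLDS: dict[tuple[str, str], float] = {
    ("day", "sbp"): 135.0,
    ("day", "dbp"): 85.0,
    ("night", "sbp"): 120.0,
    ("night", "dbp"): 70.0,
}

WBPV_INCREASED_THRESHOLD = 11.0  # mmHg
PPH_DROP_THRESHOLD = 20.0  # mmHg
PPH_WINDOW_MIN = 120
HYPO_EP_DELTA = 15.0  # mmHg below 24-h mean SBP
HYPO_AW_WINDOW_MIN = 90


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction options.

    ``day_night_fallback``: fixed clock-time (wake, sleep) windows used when
    the diary has no sleep_onset; ``None`` disables the fallback (error
    instead). ``lunch_fallback_hours``: morning-window length after awakening
    used when no diary meal at/after ``lunch_earliest`` exists.
    """

    day_night_fallback: Optional[tuple[time, time]] = (time(7, 0), time(23, 0))
    lunch_earliest: time = time(11, 0)
    lunch_fallback_hours: Optional[float] = 5.0
    sd_single_reading_is_error: bool = True


@dataclass
class DayNightSplit:
    day_readings: list[BPReading]
    night_readings: list[BPReading]
    day_hours: float
    night_hours: float
    used_fallback: bool = False


class WeightedBPV(NamedTuple):
    value: float
    increased: bool


#: LDA training-variable order: period means of all three components,
#: systolic SDs, the four loads, then the bespoke parameters.
FEATURE_COLUMNS = [
    "mean_sbp_24h",
    "mean_mbp_24h",
    "mean_dbp_24h",
    "mean_sbp_day",
    "mean_mbp_day",
    "mean_dbp_day",
    "mean_sbp_night",
    "mean_mbp_night",
    "mean_dbp_night",
    "sd_sbp_24h",
    "sd_sbp_day",
    "sd_sbp_night",
    "load_sbp_day",
    "load_dbp_day",
    "load_sbp_night",
    "load_dbp_night",
    "w_bpv",
    "pph",
    "reverse_dipping",
    "hypo_aw",
    "n_hypo_ep",
]

BINARY_FEATURES = ("pph", "reverse_dipping", "hypo_aw")


@dataclass(frozen=True)
class FeatureVector:
    mean_sbp_24h: float
    mean_mbp_24h: float
    mean_dbp_24h: float
    mean_sbp_day: float
    mean_mbp_day: float
    mean_dbp_day: float
    mean_sbp_night: float
    mean_mbp_night: float
    mean_dbp_night: float
    sd_sbp_24h: float
    sd_sbp_day: float
    sd_sbp_night: float
    load_sbp_day: float
    load_dbp_day: float
    load_sbp_night: float
    load_dbp_night: float
    w_bpv: float
    pph: bool
    reverse_dipping: bool
    hypo_aw: bool
    n_hypo_ep: int

    def __post_init__(self) -> None:
        for name in ("load_sbp_day", "load_dbp_day", "load_sbp_night", "load_dbp_night"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name}={v} outside [0, 100]")
        if self.w_bpv < 0:
            raise ValidationError(f"w_bpv={self.w_bpv} negative")
        if self.n_hypo_ep < 0:
            raise ValidationError(f"n_hypo_ep={self.n_hypo_ep} negative")
        if self.hypo_aw and self.n_hypo_ep < 1:
            raise ValidationError("hypo_aw requires n_hypo_ep >= 1")

    def to_array(self) -> np.ndarray:
        return np.array([float(getattr(self, c)) for c in FEATURE_COLUMNS])

    def to_dict(self) -> dict:
        return {c: getattr(self, c) for c in FEATURE_COLUMNS}


# ---------------------------------------------------------------------------


def _component_values(readings: Sequence[BPReading], component: Component) -> np.ndarray:
    if component == "sbp":
        return np.array([r.sbp for r in readings], dtype=float)
    if component == "dbp":
        return np.array([r.dbp for r in readings], dtype=float)
    if component == "mbp":
        return np.array([r.mbp_effective for r in readings], dtype=float)
    raise ValueError(f"unknown component {component!r}")


def split_day_night(
    recording: ABPMRecording, config: FeatureConfig = FeatureConfig()
) -> DayNightSplit:
    """Partition readings into day and night using the diary.

    Night is the union of [sleep_onset, next awakening) intervals; everything
    else is day. Durations are measured on intervals clipped to the recording
    span, so day_hours + night_hours equals the span exactly. Without a diary
    sleep_onset the configured fixed clock-time fallback is used and flagged.
    """
    if not recording.readings:
        raise ValidationError(f"{recording.patient_id}: empty recording")
    events = sorted(recording.diary, key=lambda e: e.timestamp)
    sleeps = [e.timestamp for e in events if e.kind == EventKind.SLEEP_ONSET]
    wakes = [e.timestamp for e in events if e.kind == EventKind.AWAKENING]
    used_fallback = False
    t0, t1 = recording.start, recording.end

    if not sleeps:
        if config.day_night_fallback is None:
            raise ValidationError(
                f"{recording.patient_id}: no sleep_onset in diary and fallback disabled"
            )
        wake_t, sleep_t = config.day_night_fallback
        used_fallback = True
        logger.warning(
            "%s: no diary sleep_onset; using fixed %s/%s day window",
            recording.patient_id,
            wake_t,
            sleep_t,
        )
        sleeps, wakes = [], []
        d = t0.date() - timedelta(days=1)
        while datetime.combine(d, time(0)) <= t1:
            sleeps.append(datetime.combine(d, sleep_t))
            wakes.append(datetime.combine(d, wake_t))
            d += timedelta(days=1)

    night_intervals: list[tuple[datetime, datetime]] = []
    for s in sleeps:
        nxt = [w for w in wakes if w > s]
        end = min(nxt) if nxt else t1 + timedelta(minutes=1)
        night_intervals.append((s, end))

    def in_night(ts: datetime) -> bool:
        return any(a <= ts < b for a, b in night_intervals)

    day_readings = [r for r in recording.readings if not in_night(r.timestamp)]
    night_readings = [r for r in recording.readings if in_night(r.timestamp)]
    if not day_readings or not night_readings:
        raise ValidationError(
            f"{recording.patient_id}: day/night split left an empty period "
            f"({len(day_readings)} day, {len(night_readings)} night)"
        )
    night_hours = 0.0
    for a, b in night_intervals:
        lo, hi = max(a, t0), min(b, t1)
        if hi > lo:
            night_hours += (hi - lo).total_seconds() / 3600.0
    span = recording.span_hours
    day_hours = span - night_hours
    return DayNightSplit(day_readings, night_readings, day_hours, night_hours, used_fallback)


def period_stats(
    readings: Sequence[BPReading],
    component: Component,
    config: FeatureConfig = FeatureConfig(),
) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator) of one component."""
    if len(readings) == 0:
        raise ValidationError("period_stats on empty reading list")
    values = _component_values(readings, component)
    mean = float(values.mean())
    if len(values) == 1:
        if config.sd_single_reading_is_error:
            raise ValidationError("sample SD undefined for a single reading")
        return mean, 0.0
    return mean, float(values.std(ddof=1))


def bp_load(split: DayNightSplit, period: Period, component: Component) -> float:
    """Percentage of readings at/above the period reference value."""
    readings = split.day_readings if period == "day" else split.night_readings
    if not readings:
        raise ValidationError(f"bp_load: empty {period} period")
    threshold = LOAD_THRESHOLDS[(period, component)]
    values = _component_values(readings, component)
    return 100.0 * float((values >= threshold).sum()) / len(values)


def reverse_dipping(split: DayNightSplit) -> bool:
    """True iff mean day SBP minus mean night SBP is <= 0 mmHg."""
    day_mean = _component_values(split.day_readings, "sbp").mean()
    night_mean = _component_values(split.night_readings, "sbp").mean()
    return bool(day_mean - night_mean <= 0.0)


def weighted_bpv(
    split: DayNightSplit, config: FeatureConfig = FeatureConfig()
) -> WeightedBPV:
    """Duration-weighted average of day and night systolic SDs:
    (sd_day * h_day + sd_night * h_night) / (h_day + h_night)."""
    if split.day_hours <= 0 or split.night_hours <= 0:
        raise ValidationError(
            f"degenerate period durations: day {split.day_hours} h, night {split.night_hours} h"
        )
    _, sd_day = period_stats(split.day_readings, "sbp", config)
    _, sd_night = period_stats(split.night_readings, "sbp", config)
    value = (sd_day * split.day_hours + sd_night * split.night_hours) / (
        split.day_hours + split.night_hours
    )
    return WeightedBPV(value, value > WBPV_INCREASED_THRESHOLD)


def postprandial_hypotension(
    recording: ABPMRecording,
) -> tuple[bool, list[float]]:
    """Per-meal SBP drop versus the mean of the last three pre-meal readings.

    A meal's drop is reference minus the minimum SBP in (meal, meal + 120 min];
    PPH is true iff any analysable meal drops >= 20 mmHg. Meals with fewer
    than three prior readings are skipped with a log notice; zero analysable
    meals is an error.
    """
    meals = sorted(
        e.timestamp for e in recording.diary if e.kind == EventKind.MEAL
    )
    if not meals:
        raise ValidationError(f"{recording.patient_id}: no meal events in diary")
    drops: list[float] = []
    for meal in meals:
        pre = [r.sbp for r in recording.readings if r.timestamp < meal][-3:]
        if len(pre) < 3:
            logger.warning(
                "%s: meal at %s has %d prior reading(s), skipped",
                recording.patient_id,
                meal,
                len(pre),
            )
            continue
        window_end = meal + timedelta(minutes=PPH_WINDOW_MIN)
        post = [
            r.sbp
            for r in recording.readings
            if meal < r.timestamp <= window_end
        ]
        if not post:
            logger.warning(
                "%s: meal at %s has no reading in the 120-min window, skipped",
                recording.patient_id,
                meal,
            )
            continue
        drops.append(float(np.mean(pre)) - min(post))
    if not drops:
        raise ValidationError(f"{recording.patient_id}: no analysable meal")
    return any(d >= PPH_DROP_THRESHOLD for d in drops), drops


def _first_awakening(recording: ABPMRecording) -> datetime:
    wakes = [e.timestamp for e in recording.diary if e.kind == EventKind.AWAKENING]
    if not wakes:
        raise ValidationError(f"{recording.patient_id}: no awakening event")
    return min(wakes)


def hypotensive_episodes(
    recording: ABPMRecording,
    mean_sbp_24h: float,
    config: FeatureConfig = FeatureConfig(),
) -> tuple[int, list[datetime]]:
    """Count readings in [awakening, lunch) with SBP at least 15 mmHg below
    the 24-h mean SBP; returns their timestamps.

    Lunch is the first diary meal at/after ``config.lunch_earliest`` local
    time (and not before awakening); if none exists the fallback window
    awakening + ``lunch_fallback_hours`` is used and flagged.
    """
    awakening = _first_awakening(recording)
    lunches = [
        e.timestamp
        for e in recording.diary
        if e.kind == EventKind.MEAL
        and e.timestamp >= awakening
        and e.timestamp.time() >= config.lunch_earliest
    ]
    if lunches:
        lunch = min(lunches)
    elif config.lunch_fallback_hours is not None:
        lunch = awakening + timedelta(hours=config.lunch_fallback_hours)
        logger.warning(
            "%s: no diary lunch; using awakening + %.1f h window",
            recording.patient_id,
            config.lunch_fallback_hours,
        )
    else:
        raise ValidationError(
            f"{recording.patient_id}: no lunch identifiable and fallback disabled"
        )
    threshold = mean_sbp_24h - HYPO_EP_DELTA
    times = [
        r.timestamp
        for r in recording.readings
        if awakening <= r.timestamp < lunch and r.sbp <= threshold
    ]
    return len(times), times


def awakening_hypotension(
    episode_times: Iterable[datetime], awakening: datetime
) -> bool:
    """True iff any hypotensive episode falls within 90 min of awakening
    (inclusive bounds)."""
    end = awakening + timedelta(minutes=HYPO_AW_WINDOW_MIN)
    return any(awakening <= t <= end for t in episode_times)


def extract_features(
    recording: ABPMRecording, config: FeatureConfig = FeatureConfig()
) -> FeatureVector:
    """Compose the full ABPM parameter set for one recording.

    Pure function of (readings, diary, config); any component error is
    re-raised with the patient id attached.
    """
    try:
        split = split_day_night(recording, config)
        mean24 = {}
        sd24 = {}
        day = {}
        night = {}
        for comp in ("sbp", "mbp", "dbp"):
            mean24[comp], sd24[comp] = period_stats(recording.readings, comp, config)
            day[comp] = period_stats(split.day_readings, comp, config)
            night[comp] = period_stats(split.night_readings, comp, config)
        wbpv = weighted_bpv(split, config)
        pph, _ = postprandial_hypotension(recording)
        n_ep, ep_times = hypotensive_episodes(recording, mean24["sbp"], config)
        hypo_aw = awakening_hypotension(ep_times, _first_awakening(recording))
        return FeatureVector(
            mean_sbp_24h=mean24["sbp"],
            mean_mbp_24h=mean24["mbp"],
            mean_dbp_24h=mean24["dbp"],
            mean_sbp_day=day["sbp"][0],
            mean_mbp_day=day["mbp"][0],
            mean_dbp_day=day["dbp"][0],
            mean_sbp_night=night["sbp"][0],
            mean_mbp_night=night["mbp"][0],
            mean_dbp_night=night["dbp"][0],
            sd_sbp_24h=sd24["sbp"],
            sd_sbp_day=day["sbp"][1],
            sd_sbp_night=night["sbp"][1],
            load_sbp_day=bp_load(split, "day", "sbp"),
            load_dbp_day=bp_load(split, "day", "dbp"),
            load_sbp_night=bp_load(split, "night", "sbp"),
            load_dbp_night=bp_load(split, "night", "dbp"),
            w_bpv=wbpv.value,
            pph=pph,
            reverse_dipping=reverse_dipping(split),
            hypo_aw=hypo_aw,
            n_hypo_ep=n_ep,
        )
    except ValidationError as exc:
        raise ValidationError(f"[{recording.patient_id}] {exc}") from exc
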