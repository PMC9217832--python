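"""Synthetic 24-h ABPM cohorts with the group structure of a PD population
with and without autonomic failure.

Each patient draws day and night systolic "true" means from group-level
bivariate normal distributions (correlated, so the day-night difference has
a realistic spread), then emits a 15-min-cadence reading series as period
mean plus independent Gaussian within-period noise whose SD is itself a
patient-level draw (so between-patient variability-of-variability, and hence
the prevalence of "increased SD" flags, is reproduced). Morning hypotensive
dips (Poisson-many rectangular one-to-two-slot depressions at least 20 mmHg
below the nominal 24-h mean) are superimposed between awakening and lunch;
with a group-specific probability a postprandial trough is inserted after
lunch or dinner (never after breakfast, so the morning episode window stays
clean). DBP is SBP minus a patient-level pulse pressure; diary events sit at
configured clock times. The autonomic-failure label is derived from sampled
CASS subscores through the same rule the evaluation uses.

Default group parameters are calibrated to the clinical cohort the package
targets (n=80, 36% AF prevalence, day/night SBP 122+-10 / 109+-11 mmHg in
AF-negative and 118+-8 / 122+-17 in AF-positive patients, morning-dip rates
0.4 and 3.4). No within-day autocorrelation is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as abpm_io
from .cart import CASSInput, af_diagnosis
from .io import (
    ABPMRecording,
    BPReading,
    DiaryEvent,
    EventKind,
    PatientCovariates,
    Sex,
    ValidationError,
)

__all__ = [
    "GroupParams",
    "CohortConfig",
    "SyntheticCohort",
    "generate_patient",
    "generate_cohort",
    "write_cohort",
    "noise_free",
    "AF_NEG_DEFAULTS",
    "AF_POS_DEFAULTS",
]


@dataclass(frozen=True)
class GroupParams:
    """Patient-level distributions for one diagnostic group. BP in mmHg,
    rates per recording, noise SDs are the distribution of each patient's
    within-period reading SD."""

    day_sbp_mean: float
    day_sbp_sd: float
    night_sbp_mean: float
    night_sbp_sd: float
    day_night_corr: float
    day_noise_mean: float
    day_noise_sd: float
    night_noise_mean: float
    night_noise_sd: float
    pph_prob: float
    hypo_ep_rate: float  # Poisson mean of injected morning dip events
    age_mean: float
    age_sd: float
    duration_mean: float
    duration_sd: float
    ledd_mean: float
    ledd_sd: float
    female_prob: float


AF_NEG_DEFAULTS = GroupParams(
    day_sbp_mean=122.0,
    day_sbp_sd=10.0,
    night_sbp_mean=109.0,
    night_sbp_sd=11.0,
    day_night_corr=0.5,
    day_noise_mean=12.0,
    day_noise_sd=3.0,
    night_noise_mean=9.0,
    night_noise_sd=2.5,
    pph_prob=0.45,
    hypo_ep_rate=0.4,
    age_mean=61.0,
    age_sd=10.0,
    duration_mean=5.5,
    duration_sd=3.0,
    ledd_mean=657.0,
    ledd_sd=326.0,
    female_prob=0.33,
)

AF_POS_DEFAULTS = GroupParams(
    day_sbp_mean=118.0,
    day_sbp_sd=8.0,
    night_sbp_mean=122.0,
    night_sbp_sd=17.0,
    day_night_corr=0.5,
    day_noise_mean=14.0,
    day_noise_sd=4.0,
    night_noise_mean=11.0,
    night_noise_sd=3.0,
    pph_prob=0.58,
    hypo_ep_rate=3.4,
    age_mean=67.0,
    age_sd=10.0,
    duration_mean=7.0,
    duration_sd=4.5,
    ledd_mean=694.0,
    ledd_sd=403.0,
    female_prob=0.31,
)


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 80
    af_prevalence: float = 0.3625
    seed: int = 0
    cadence_min: int = 15
    wake_time: time = time(7, 0)
    sleep_time: time = time(23, 0)
    meal_times: tuple[time, ...] = (time(8, 0), time(13, 0), time(20, 0))
    dip_depth_range: tuple[float, float] = (20.0, 30.0)
    pph_drop_range: tuple[float, float] = (25.0, 35.0)
    pulse_pressure_mean: float = 45.0
    pulse_pressure_sd: float = 5.0
    start_date: datetime = datetime(2021, 3, 1, 7, 0)
    round_to_integer: bool = True
    af_neg: GroupParams = AF_NEG_DEFAULTS
    af_pos: GroupParams = AF_POS_DEFAULTS

    def validate(self) -> None:
        if not (0.0 <= self.af_prevalence <= 1.0):
            raise ValidationError("af_prevalence must be a probability")
        if (24 * 60) % self.cadence_min != 0:
            raise ValidationError("cadence must divide 24 h")
        for g in (self.af_neg, self.af_pos):
            if min(g.day_sbp_sd, g.night_sbp_sd, g.day_noise_sd, g.night_noise_sd) < 0:
                raise ValidationError("group SDs must be >= 0")
            if not (0 <= g.pph_prob <= 1):
                raise ValidationError("pph_prob must be a probability")
        if self.dip_depth_range[0] < 15.0:
            raise ValidationError("dip depth must exceed the 15 mmHg episode criterion")


def noise_free(config: CohortConfig) -> CohortConfig:
    """The same cohort with all within-period noise and patient-level spread
    of noise SD removed (construction-guarantee checks)."""
    return replace(
        config,
        af_neg=replace(
            config.af_neg, day_noise_mean=0, day_noise_sd=0, night_noise_mean=0, night_noise_sd=0
        ),
        af_pos=replace(
            config.af_pos, day_noise_mean=0, day_noise_sd=0, night_noise_mean=0, night_noise_sd=0
        ),
        round_to_integer=False,
    )


@dataclass
class SyntheticCohort:
    recordings: list[ABPMRecording]
    covariates: list[PatientCovariates]
    truth: list[dict]


def _sample_cass(af: bool, rng: np.random.Generator) -> CASSInput:
    if af:
        cardio = int(rng.choice([0, 1, 2], p=[0.35, 0.45, 0.20]))
        adren = int(rng.choice([1, 2, 3], p=[0.30, 0.50, 0.20]))
        if cardio + adren < 2:
            adren = 2
    else:
        cardio, adren = [(0, 0), (0, 1), (1, 0)][int(rng.choice(3, p=[0.5, 0.25, 0.25]))]
    return CASSInput(cardio, adren)


def generate_patient(
    af_positive: bool,
    config: CohortConfig,
    rng: np.random.Generator,
    patient_id: str,
) -> tuple[ABPMRecording, PatientCovariates, dict]:
    """One synthetic patient: recording + covariates + generating truth."""
    g = config.af_pos if af_positive else config.af_neg
    cadence = timedelta(minutes=config.cadence_min)
    start = config.start_date.replace(
        hour=config.wake_time.hour, minute=config.wake_time.minute
    )
    n_slots = (24 * 60) // config.cadence_min
    timestamps = [start + i * cadence for i in range(n_slots)]

    # patient-level true period means, correlated day/night
    cov = g.day_night_corr * g.day_sbp_sd * g.night_sbp_sd
    day_mean, night_mean = rng.multivariate_normal(
        [g.day_sbp_mean, g.night_sbp_mean],
        [[g.day_sbp_sd**2, cov], [cov, g.night_sbp_sd**2]],
    )
    day_noise = max(0.0, rng.normal(g.day_noise_mean, g.day_noise_sd)) if g.day_noise_mean else 0.0
    night_noise = (
        max(0.0, rng.normal(g.night_noise_mean, g.night_noise_sd)) if g.night_noise_mean else 0.0
    )

    day0 = start.date()
    sleep_dt = datetime.combine(day0, config.sleep_time)
    wake2_dt = datetime.combine(day0 + timedelta(days=1), config.wake_time)
    meals = [datetime.combine(day0, t) for t in config.meal_times]
    lunch = next(t for t in meals if t.time() >= time(11, 0))

    is_night = np.array([sleep_dt <= ts < wake2_dt for ts in timestamps])
    night_hours = is_night.sum() * config.cadence_min / 60.0
    day_hours = 24.0 - night_hours
    nominal_24h_mean = (day_mean * day_hours + night_mean * night_hours) / 24.0

    sbp = np.where(is_night, night_mean, day_mean) + rng.normal(
        0.0, 1.0, n_slots
    ) * np.where(is_night, night_noise, day_noise)

    # morning dips: Poisson-many events of 1-2 consecutive slots in [wake, lunch)
    morning_idx = [
        i for i, ts in enumerate(timestamps) if start <= ts < lunch and not is_night[i]
    ]
    # total dip slots capped at 12 so the summed depressions can never pull the
    # empirical 24-h mean far enough to leave any dip above the detection
    # threshold (depth >= 20 while the mean shifts by < 5 mmHg)
    n_requested = int(rng.poisson(g.hypo_ep_rate))
    dip_slots: list[int] = []
    free = list(morning_idx)
    n_events = 0
    for _ in range(n_requested):
        if not free or len(dip_slots) >= 12:
            break
        i = int(rng.choice(free))
        slots = [i]
        if rng.random() < 0.5 and (i + 1) in free and len(dip_slots) < 11:
            slots.append(i + 1)
        for s in slots:
            free.remove(s)
            dip_slots.append(s)
        n_events += 1
    for s in dip_slots:
        depth = rng.uniform(*config.dip_depth_range)
        sbp[s] = nominal_24h_mean - depth

    # postprandial trough after lunch or dinner
    pph_slots: list[int] = []
    pph_inserted = rng.random() < g.pph_prob
    if pph_inserted:
        candidates = [m for m in meals if m >= lunch]
        meal = candidates[int(rng.choice(len(candidates)))]
        window = [
            i
            for i, ts in enumerate(timestamps)
            if meal < ts <= meal + timedelta(minutes=120) and i not in dip_slots
        ]
        trough = int(rng.choice(window[2:] or window))
        drop = rng.uniform(*config.pph_drop_range)
        for s in (trough, trough + 1):
            if s in window:
                sbp[s] = day_mean - drop
                pph_slots.append(s)

    # the configured day mean is an *observed* (post-dip) group value, so the
    # deficit the injected depressions remove from the daytime average is
    # redistributed over the unmodified day readings; without this the
    # extracted day mean would sit systematically below the configured one
    modified = set(dip_slots) | set(pph_slots)
    day_idx = [i for i in range(n_slots) if not is_night[i]]
    unmodified_day = [i for i in day_idx if i not in modified]
    deficit = sum(day_mean - sbp[s] for s in modified)
    if unmodified_day and deficit > 0:
        sbp[unmodified_day] += deficit / len(unmodified_day)

    pulse_pressure = max(25.0, rng.normal(config.pulse_pressure_mean, config.pulse_pressure_sd))
    dbp = sbp - pulse_pressure
    hr = rng.normal(72.0, 9.0) + rng.normal(0.0, 4.0, n_slots)

    if config.round_to_integer:
        sbp, dbp, hr = np.round(sbp), np.round(dbp), np.round(hr)
    sbp = np.clip(sbp, 41, 300)
    dbp = np.clip(dbp, 21, np.minimum(200, sbp - 1))

    readings = [
        BPReading(ts, float(s), float(d), None, float(h))
        for ts, s, d, h in zip(timestamps, sbp, dbp, hr)
    ]
    diary = [
        DiaryEvent(start, EventKind.AWAKENING),
        *[DiaryEvent(m, EventKind.MEAL) for m in meals],
        DiaryEvent(sleep_dt, EventKind.SLEEP_ONSET),
        DiaryEvent(wake2_dt, EventKind.AWAKENING),
    ]
    recording = ABPMRecording(patient_id, readings, diary)

    cass = _sample_cass(af_positive, rng)
    covariates = PatientCovariates(
        patient_id=patient_id,
        age=float(np.round(np.clip(rng.normal(g.age_mean, g.age_sd), 35, 95))),
        sex=Sex.F if rng.random() < g.female_prob else Sex.M,
        disease_duration=float(np.round(np.clip(rng.normal(g.duration_mean, g.duration_sd), 2, 40), 1)),
        ledd=float(np.round(np.clip(rng.normal(g.ledd_mean, g.ledd_sd), 0, 3000))),
        cardiovagal_score=cass.cardiovagal_score,
        adrenergic_score=cass.adrenergic_score,
        af_label=af_diagnosis(cass),
    )
    truth = {
        "patient_id": patient_id,
        "af": af_positive,
        "day_mean": day_mean,
        "night_mean": night_mean,
        "day_noise_sd": day_noise,
        "night_noise_sd": night_noise,
        "n_dip_events": n_events,
        "n_dip_slots": len(dip_slots),
        "dip_times": [timestamps[s] for s in sorted(dip_slots)],
        "pph_inserted": pph_inserted,
        "pulse_pressure": pulse_pressure,
    }
    return recording, covariates, truth


def generate_cohort(config: CohortConfig = CohortConfig()) -> SyntheticCohort:
    """n independent patients; group assignment Bernoulli(af_prevalence).

    Each patient consumes an independent substream spawned from the seed, so
    enlarging the cohort never perturbs earlier patients.
    """
    config.validate()
    if config.n_patients < 4:
        raise ValidationError("need n_patients >= 4 so both classes can appear downstream")
    streams = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    cohort = SyntheticCohort([], [], [])
    width = len(str(config.n_patients))
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        af = bool(rng.random() < config.af_prevalence)
        rec, cov, truth = generate_patient(af, config, rng, f"pt{i + 1:0{width}d}")
        cohort.recordings.append(rec)
        cohort.covariates.append(cov)
        cohort.truth.append(truth)
    return cohort


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> Path:
    """Write a cohort directory in the canonical CSV formats."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in cohort.recordings:
        abpm_io.write_recording(rec, directory / f"{rec.patient_id}.csv")
    abpm_io.write_covariates(cohort.covariates, directory / "covariates.csv")
    return directory
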