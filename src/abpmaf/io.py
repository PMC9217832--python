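"""Reading, validating and writing ambulatory blood-pressure recordings.

The canonical on-disk layout is device-neutral plain CSV:

* ``<patient_id>.csv`` — one BP reading per row, header
  ``timestamp,sbp,dbp,mbp,hr``; an empty cell is a missing optional value.
* ``<patient_id>.diary.csv`` — diary events, header ``timestamp,kind`` with
  ``kind`` one of ``sleep_onset``, ``awakening``, ``meal``.
* ``covariates.csv`` — one row per patient, header
  ``patient_id,age,sex,disease_duration,ledd,cardiovagal_score,adrenergic_score,af_label``.

Timestamps are ISO 8601 local clock time at minute resolution; no time-zone
arithmetic is performed. All downstream modules consume only the types
defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from enum import Enum
from pathlib import Path
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "IOConfig",
    "BPReading",
    "EventKind",
    "DiaryEvent",
    "ABPMRecording",
    "PatientCovariates",
    "read_recording",
    "write_recording",
    "read_covariates",
    "write_covariates",
    "read_cohort",
]


class FormatError(ValueError):
    """A file does not conform to the canonical CSV dialect."""


class ValidationError(ValueError):
    """A parsed object violates a domain invariant."""


@dataclass(frozen=True)
class IOConfig:
    """Reader configuration.

    ``min_valid_fraction`` is the minimum fraction of expected measurement
    slots (at ``expected_cadence_min`` cadence over the recording span) that
    must hold a valid reading for the recording to be accepted; 0.70 is a
    guideline-typical completeness criterion.
    """

    min_valid_fraction: float = 0.70
    expected_cadence_min: int = 15
    min_span_hours: float = 20.0
    max_span_hours: float = 30.0


@dataclass(frozen=True)
class BPReading:
    """A single cuff measurement: systolic/diastolic in mmHg, optional mean
    arterial pressure and heart rate."""

    timestamp: datetime
    sbp: float
    dbp: float
    mbp: Optional[float] = None
    hr: Optional[float] = None

    def validate(self) -> None:
        if not self.dbp > 0 or not self.sbp > self.dbp:
            raise ValidationError(
                f"require sbp > dbp > 0, got sbp={self.sbp}, dbp={self.dbp}"
            )
        if not (40 <= self.sbp <= 300):
            raise ValidationError(f"sbp {self.sbp} outside plausible range [40, 300]")
        if not (20 <= self.dbp <= 200):
            raise ValidationError(f"dbp {self.dbp} outside plausible range [20, 200]")
        if self.mbp is not None and not (self.dbp <= self.mbp <= self.sbp):
            raise ValidationError(
                f"mbp {self.mbp} outside [dbp, sbp] = [{self.dbp}, {self.sbp}]"
            )

    @property
    def mbp_effective(self) -> float:
        """Mean arterial pressure: stored value if present, otherwise the
        standard one-third-pulse-pressure estimate dbp + (sbp - dbp)/3."""
        if self.mbp is not None:
            return self.mbp
        return self.dbp + (self.sbp - self.dbp) / 3.0


class EventKind(str, Enum):
    SLEEP_ONSET = "sleep_onset"
    AWAKENING = "awakening"
    MEAL = "meal"


@dataclass(frozen=True)
class DiaryEvent:
    timestamp: datetime
    kind: EventKind


@dataclass
class ABPMRecording:
    """One patient's 24-h recording: ordered readings plus diary events.

    ``n_malformed_rows`` counts rows the reader could not parse (reported,
    never silently dropped without notice); it does not participate in
    equality so that write→read round-trips compare clean.
    """

    patient_id: str
    readings: list[BPReading]
    diary: list[DiaryEvent] = field(default_factory=list)
    n_malformed_rows: int = field(default=0, compare=False)

    @property
    def start(self) -> datetime:
        return self.readings[0].timestamp

    @property
    def end(self) -> datetime:
        return self.readings[-1].timestamp

    @property
    def span_hours(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0

    def sorted(self) -> "ABPMRecording":
        return replace(
            self,
            readings=sorted(self.readings, key=lambda r: r.timestamp),
            diary=sorted(self.diary, key=lambda e: e.timestamp),
        )

    def validate(self, config: IOConfig = IOConfig()) -> None:
        if not self.readings:
            raise ValidationError(f"{self.patient_id}: recording has no readings")
        for i, r in enumerate(self.readings):
            try:
                r.validate()
            except ValidationError as exc:
                raise ValidationError(
                    f"{self.patient_id}: reading {i} at {r.timestamp}: {exc}"
                ) from exc
        times = [r.timestamp for r in self.readings]
        for i in range(1, len(times)):
            if times[i] <= times[i - 1]:
                raise ValidationError(
                    f"{self.patient_id}: readings not strictly increasing at index {i}"
                    f" ({times[i - 1]} -> {times[i]})"
                )
        span = self.span_hours
        if not (config.min_span_hours <= span <= config.max_span_hours):
            raise ValidationError(
                f"{self.patient_id}: span {span:.2f} h outside "
                f"[{config.min_span_hours}, {config.max_span_hours}] h"
            )
        if not any(e.kind == EventKind.AWAKENING for e in self.diary):
            raise ValidationError(f"{self.patient_id}: diary has no awakening event")
        expected_slots = span * 60.0 / config.expected_cadence_min + 1
        fraction = len(self.readings) / expected_slots
        if fraction < config.min_valid_fraction:
            raise ValidationError(
                f"{self.patient_id}: only {len(self.readings)} of ~{expected_slots:.0f}"
                f" expected readings ({fraction:.0%} < {config.min_valid_fraction:.0%})"
            )


class Sex(str, Enum):
    M = "M"
    F = "F"


@dataclass(frozen=True)
class PatientCovariates:
    """Clinical covariates: demographics, Parkinson's disease duration,
    levodopa-equivalent daily dose, and the autonomic-testing reference
    (CASS subscores and/or the dichotomous autonomic-failure label)."""

    patient_id: str
    age: float
    sex: Sex
    disease_duration: float
    ledd: float
    cardiovagal_score: Optional[int] = None
    adrenergic_score: Optional[int] = None
    af_label: Optional[bool] = None

    def validate(self) -> None:
        if self.af_label is None and (
            self.cardiovagal_score is None or self.adrenergic_score is None
        ):
            raise ValidationError(
                f"{self.patient_id}: af_label absent requires both CASS subscores"
            )
        for name in ("cardiovagal_score", "adrenergic_score"):
            v = getattr(self, name)
            if v is not None and (v < 0 or int(v) != v):
                raise ValidationError(f"{self.patient_id}: {name}={v} must be an integer >= 0")


# ---------------------------------------------------------------------------
# serialization helpers

_TS_FMT = "%Y-%m-%dT%H:%M"


def _format_number(v: Optional[float]) -> str:
    if v is None:
        return ""
    f = float(v)
    if f.is_integer():
        return str(int(f))
    return repr(f)


def _parse_timestamp(raw: str) -> datetime:
    ts = datetime.fromisoformat(raw.strip())
    return ts.replace(second=0, microsecond=0)


def _diary_path(path: Path) -> Path:
    return path.with_name(path.stem + ".diary.csv")


def read_recording(path: str | Path, config: IOConfig = IOConfig()) -> ABPMRecording:
    """Read ``<patient_id>.csv`` (and its sibling diary file, if present),
    returning a validated, time-sorted :class:`ABPMRecording`.

    Rows that cannot be parsed (non-numeric or missing mandatory cells) are
    counted, logged and skipped; rows that parse but violate a reading
    invariant raise :class:`ValidationError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    patient_id = path.stem
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed CSV structure
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = {"timestamp", "sbp", "dbp"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {sorted(missing)}")

    readings: list[BPReading] = []
    n_malformed = 0
    for idx, row in df.iterrows():
        try:
            ts = _parse_timestamp(row["timestamp"])
            sbp = float(row["sbp"])
            dbp = float(row["dbp"])
        except (ValueError, TypeError):
            n_malformed += 1
            logger.warning("%s: row %d malformed, skipped: %s", path, idx, dict(row))
            continue
        mbp = float(row["mbp"]) if row.get("mbp", "") not in ("", None) else None
        hr = float(row["hr"]) if row.get("hr", "") not in ("", None) else None
        reading = BPReading(ts, sbp, dbp, mbp, hr)
        try:
            reading.validate()
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from exc
        readings.append(reading)
    if n_malformed:
        logger.warning("%s: %d malformed row(s) skipped", path, n_malformed)

    diary: list[DiaryEvent] = []
    dpath = _diary_path(path)
    if dpath.exists():
        ddf = pd.read_csv(dpath, dtype=str, keep_default_na=False)
        if {"timestamp", "kind"} - set(ddf.columns):
            raise FormatError(f"{dpath}: diary requires columns timestamp,kind")
        for idx, row in ddf.iterrows():
            try:
                kind = EventKind(row["kind"].strip())
            except ValueError as exc:
                raise FormatError(f"{dpath}: row {idx}: unknown event kind {row['kind']!r}") from exc
            diary.append(DiaryEvent(_parse_timestamp(row["timestamp"]), kind))

    rec = ABPMRecording(patient_id, readings, diary, n_malformed_rows=n_malformed).sorted()
    rec.validate(config)
    return rec


def write_recording(recording: ABPMRecording, path: str | Path) -> None:
    """Write a recording (and its diary, if any) in the canonical CSV dialect.

    ``read_recording(write_recording(x)) == x`` field-for-field for any valid
    recording. Nothing is written for an invalid recording.
    """
    if not recording.readings:
        raise ValidationError(f"{recording.patient_id}: refusing to write empty recording")
    path = Path(path)
    lines = ["timestamp,sbp,dbp,mbp,hr"]
    for r in recording.readings:
        lines.append(
            ",".join(
                [
                    r.timestamp.strftime(_TS_FMT),
                    _format_number(r.sbp),
                    _format_number(r.dbp),
                    _format_number(r.mbp),
                    _format_number(r.hr),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    if recording.diary:
        dlines = ["timestamp,kind"]
        for e in recording.diary:
            dlines.append(f"{e.timestamp.strftime(_TS_FMT)},{e.kind.value}")
        _diary_path(path).write_text("\n".join(dlines) + "\n", encoding="utf-8")


def _parse_bool(raw: str) -> Optional[bool]:
    raw = raw.strip()
    if raw == "":
        return None
    if raw in ("0", "1"):
        return bool(int(raw))
    raise FormatError(f"boolean cell must be 0, 1 or empty, got {raw!r}")


COVARIATE_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "disease_duration",
    "ledd",
    "cardiovagal_score",
    "adrenergic_score",
    "af_label",
]


def read_covariates(path: str | Path) -> list[PatientCovariates]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(COVARIATE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    out: list[PatientCovariates] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        pid = row["patient_id"].strip()
        if pid in seen:
            raise FormatError(f"{path}: duplicate patient_id {pid!r}")
        seen.add(pid)
        cov = PatientCovariates(
            patient_id=pid,
            age=float(row["age"]),
            sex=Sex(row["sex"].strip()),
            disease_duration=float(row["disease_duration"]),
            ledd=float(row["ledd"]),
            cardiovagal_score=(
                int(row["cardiovagal_score"]) if row["cardiovagal_score"].strip() else None
            ),
            adrenergic_score=(
                int(row["adrenergic_score"]) if row["adrenergic_score"].strip() else None
            ),
            af_label=_parse_bool(row["af_label"]),
        )
        cov.validate()
        out.append(cov)
    return out


def write_covariates(covariates: list[PatientCovariates], path: str | Path) -> None:
    lines = [",".join(COVARIATE_COLUMNS)]
    for c in covariates:
        lines.append(
            ",".join(
                [
                    c.patient_id,
                    _format_number(c.age),
                    c.sex.value,
                    _format_number(c.disease_duration),
                    _format_number(c.ledd),
                    "" if c.cardiovagal_score is None else str(c.cardiovagal_score),
                    "" if c.adrenergic_score is None else str(c.adrenergic_score),
                    "" if c.af_label is None else str(int(c.af_label)),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_cohort(
    recordings_dir: str | Path,
    covariates_path: str | Path,
    config: IOConfig = IOConfig(),
) -> list[tuple[ABPMRecording, PatientCovariates]]:
    """Pair every covariates row with its recording file by patient_id.

    Pairs are returned in covariates-file order. Unmatched ids on either side
    (covariates row without recording, or orphan recording file) are errors.
    """
    recordings_dir = Path(recordings_dir)
    covariates_path = Path(covariates_path)
    covariates = read_covariates(covariates_path)
    recording_files = {
        p.stem: p
        for p in sorted(recordings_dir.glob("*.csv"))
        if not p.name.endswith(".diary.csv")
        and p.resolve() != covariates_path.resolve()
        and p.name != "covariates.csv"
    }
    pairs: list[tuple[ABPMRecording, PatientCovariates]] = []
    for cov in covariates:
        if cov.patient_id not in recording_files:
            raise ValidationError(
                f"covariates row {cov.patient_id!r} has no recording file in {recordings_dir}"
            )
        pairs.append((read_recording(recording_files.pop(cov.patient_id), config), cov))
    if recording_files:
        raise ValidationError(
            f"orphan recording file(s) without covariates: {sorted(recording_files)}"
        )
    return pairs
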