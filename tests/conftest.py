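"""Shared builders for synthetic ABPM recordings used across the suite."""

from __future__ import annotations

from datetime import datetime, timedelta

import pytest
from hypothesis import settings

from abpmaf.io import ABPMRecording, BPReading, DiaryEvent, EventKind

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")

START = datetime(2021, 3, 1, 7, 0)  # awakening; recording runs 24 h from here


def standard_diary(start: datetime = START) -> list[DiaryEvent]:
    """Awakening 07:00, meals 08:00/13:00/20:00, sleep 23:00, awakening 07:00."""
    day = start.date()
    at = lambda h, m=0: datetime(day.year, day.month, day.day, h, m)
    return [
        DiaryEvent(at(7), EventKind.AWAKENING),
        DiaryEvent(at(8), EventKind.MEAL),
        DiaryEvent(at(13), EventKind.MEAL),
        DiaryEvent(at(20), EventKind.MEAL),
        DiaryEvent(at(23), EventKind.SLEEP_ONSET),
        DiaryEvent(at(7) + timedelta(days=1), EventKind.AWAKENING),
    ]


def make_recording(
    sbp_values,
    dbp_offset: float = 45.0,
    start: datetime = START,
    cadence_min: int = 15,
    diary=None,
    patient_id: str = "p1",
    hr: float | None = None,
) -> ABPMRecording:
    """A recording from an SBP series at fixed cadence; DBP = SBP - offset."""
    readings = [
        BPReading(
            start + i * timedelta(minutes=cadence_min),
            float(s),
            float(s) - dbp_offset,
            None,
            hr,
        )
        for i, s in enumerate(sbp_values)
    ]
    return ABPMRecording(
        patient_id, readings, standard_diary(start) if diary is None else diary
    )


def flat_recording(sbp: float = 110.0, dbp: float = 65.0) -> ABPMRecording:
    """96 identical readings over 24 h (all SDs zero, all loads zero)."""
    readings = [
        BPReading(START + i * timedelta(minutes=15), sbp, dbp) for i in range(96)
    ]
    return ABPMRecording("flat", readings, standard_diary())


@pytest.fixture
def recording_96():
    """Constant day (120) / lower night (105) profile, 96 readings."""
    day, night = 120.0, 105.0
    values = [day] * 64 + [night] * 32  # 07:00-23:00 day, 23:00-07:00 night
    return make_recording(values)
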