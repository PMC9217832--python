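"""Interpretation of cardiovascular autonomic reflex testing (CART).

The reference diagnosis of autonomic failure (AF) comes from autonomic
testing scored with a modified Composite Autonomic Symptom Score (CASS)
omitting the sudomotor component: AF is present when the cardiovagal plus
adrenergic subscores sum to at least 2. The subscores themselves are inputs
(their derivation from deep-breathing / Valsalva / tilt waveforms is outside
this package); the tilt-table consensus rules for orthostatic hypotension
and supine hypertension are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .io import ValidationError

__all__ = [
    "TiltPhase",
    "TiltMeasurement",
    "CASSInput",
    "detect_oh",
    "detect_sh",
    "af_diagnosis",
]

OH_SBP_DROP = 20.0  # mmHg
OH_DBP_DROP = 10.0  # mmHg
OH_WINDOW_MIN = 3.0
SH_SBP = 140.0  # mmHg
SH_DBP = 90.0  # mmHg
AF_CASS_THRESHOLD = 2


class TiltPhase(str, Enum):
    SUPINE_BASELINE = "supine_baseline"
    STANDING = "standing"


@dataclass(frozen=True)
class TiltMeasurement:
    """A cuff measurement during head-up tilt: baseline after >= 5 min supine
    rest (minutes_from_tilt = 0), standing at the 1/3/5-min protocol marks."""

    phase: TiltPhase
    minutes_from_tilt: float
    sbp: float
    dbp: float


@dataclass(frozen=True)
class CASSInput:
    cardiovagal_score: int
    adrenergic_score: int

    def __post_init__(self) -> None:
        if self.cardiovagal_score < 0 or self.adrenergic_score < 0:
            raise ValidationError("CASS subscores must be non-negative integers")


def detect_oh(baseline: TiltMeasurement, standing: Sequence[TiltMeasurement]) -> bool:
    """Orthostatic hypotension: a sustained SBP drop >= 20 mmHg or DBP drop
    >= 10 mmHg within 3 min of standing.

    "Sustained" over the discrete protocol schedule means the drop criterion
    holds at every measurement from its first occurrence through the last
    measurement at or before 3 min; measurements after 3 min are ignored.
    """
    within = sorted(
        (m for m in standing if m.minutes_from_tilt <= OH_WINDOW_MIN),
        key=lambda m: m.minutes_from_tilt,
    )
    if not within:
        raise ValidationError("no standing measurement within 3 min of tilt")
    met = [
        (baseline.sbp - m.sbp >= OH_SBP_DROP) or (baseline.dbp - m.dbp >= OH_DBP_DROP)
        for m in within
    ]
    if not any(met):
        return False
    first = met.index(True)
    return all(met[first:])


def detect_sh(supine_readings: Sequence[TiltMeasurement]) -> bool:
    """Supine hypertension: any reading after >= 5 min supine rest with
    SBP >= 140 and/or DBP >= 90 mmHg."""
    if not supine_readings:
        raise ValidationError("no supine readings")
    return any(m.sbp >= SH_SBP or m.dbp >= SH_DBP for m in supine_readings)


def af_diagnosis(cass: CASSInput) -> bool:
    """Autonomic failure: cardiovagal + adrenergic CASS subscores >= 2."""
    return cass.cardiovagal_score + cass.adrenergic_score >= AF_CASS_THRESHOLD
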