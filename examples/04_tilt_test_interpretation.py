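"""Interpret a head-up tilt test and the CASS-based diagnosis.

Applies the consensus rules for orthostatic hypotension (sustained SBP drop
>= 20 or DBP drop >= 10 mmHg within 3 min of standing) and supine
hypertension (>= 140/90 mmHg after 5 min rest), then the autonomic-failure
rule on the modified CASS subscores.
"""

from abpmaf.cart import (
    CASSInput,
    TiltMeasurement,
    TiltPhase,
    af_diagnosis,
    detect_oh,
    detect_sh,
)

baseline = TiltMeasurement(TiltPhase.SUPINE_BASELINE, 0, 132.0, 84.0)
standing = [
    TiltMeasurement(TiltPhase.STANDING, 1, 108.0, 76.0),
    TiltMeasurement(TiltPhase.STANDING, 3, 105.0, 72.0),
    TiltMeasurement(TiltPhase.STANDING, 5, 118.0, 80.0),
]

print(f"baseline {baseline.sbp:.0f}/{baseline.dbp:.0f} mmHg; standing: "
      + ", ".join(f"{m.minutes_from_tilt:.0f}min {m.sbp:.0f}/{m.dbp:.0f}" for m in standing))
print(f"orthostatic hypotension: {detect_oh(baseline, standing)}")
print(f"supine hypertension:     {detect_sh([baseline])}")

cass = CASSInput(cardiovagal_score=1, adrenergic_score=2)
print(f"CASS cardiovagal {cass.cardiovagal_score} + adrenergic "
      f"{cass.adrenergic_score} -> autonomic failure: {af_diagnosis(cass)}")
# A sustained 24-27 mmHg systolic fall within 3 min is orthostatic
# hypotension; subscores summing to >= 2 meet the autonomic-failure rule.
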