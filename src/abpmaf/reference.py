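"""Summary 2x2 counts from the clinical cohort the package is calibrated to.

The original study population was 80 consecutive Parkinson's disease
patients, 29 of whom (36%) had autonomic failure (AF) on autonomic reflex
testing. Patient-level recordings were not deposited; what is reproducible
from the published summary is the per-parameter 2x2 contingency tables
(parameter present/absent x AF present/absent), from which the diagnostic
metrics and odds ratios can be recomputed. Counts are stored as
:class:`~abpmaf.stats_eval.ConfusionCounts` with the parameter as the test
and AF as the reference diagnosis (tp = AF+ with the parameter, etc.).
"""

from __future__ import annotations

from .stats_eval import ConfusionCounts

__all__ = ["N_PATIENTS", "N_AF_POSITIVE", "PARAMETER_COUNTS"]

N_PATIENTS = 80
N_AF_POSITIVE = 29

#: parameter -> 2x2 counts (tp: AF+ with parameter, fp: AF- with parameter,
#: fn: AF+ without, tn: AF- without); AF- column n=51, AF+ column n=29
PARAMETER_COUNTS: dict[str, ConfusionCounts] = {
    "reverse_dipping": ConfusionCounts(tp=17, fp=5, fn=12, tn=46),
    "hypo_aw": ConfusionCounts(tp=13, fp=4, fn=16, tn=47),
    "sd_day_sbp_gt16": ConfusionCounts(tp=10, fp=4, fn=19, tn=47),
    "w_bpv_gt11": ConfusionCounts(tp=20, fp=25, fn=9, tn=26),
    "pph": ConfusionCounts(tp=17, fp=23, fn=12, tn=28),
}
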