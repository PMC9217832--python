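"""abpmaf: autonomic-failure screening from 24-h ambulatory BP monitoring.

The pipeline: read 24-h ABPM recordings with their patient diaries
(:mod:`abpmaf.io`), derive the circadian BP parameter set — period means and
SDs, BP loads, reverse dipping, weighted BP variability, postprandial
hypotension, morning hypotensive episodes and awakening hypotension
(:mod:`abpmaf.features`) — and classify autonomic failure with a two-class
linear discriminant against the autonomic-testing reference labels
(:mod:`abpmaf.model`, :mod:`abpmaf.cart`), with full diagnostic-accuracy
statistics (:mod:`abpmaf.stats_eval`). :mod:`abpmaf.synth` generates
synthetic cohorts with the clinical group structure so the whole pipeline is
testable without patient data.
"""

from .cart import CASSInput, TiltMeasurement, TiltPhase, af_diagnosis, detect_oh, detect_sh
from .features import (
    FEATURE_COLUMNS,
    FeatureConfig,
    FeatureVector,
    extract_features,
    split_day_night,
)
from .io import (
    ABPMRecording,
    BPReading,
    DiaryEvent,
    EventKind,
    FormatError,
    IOConfig,
    PatientCovariates,
    Sex,
    ValidationError,
    read_cohort,
    read_recording,
    write_recording,
)
from .model import CohortTable, LDAModel, evaluate, fit_lda, predict, rank_single_features
from .stats_eval import (
    ConfusionCounts,
    DiagnosticReport,
    ROCResult,
    confusion_metrics,
    group_compare,
    logistic_fit,
    odds_ratio_2x2,
    proportion_ci,
    roc_analysis,
)
from .synth import CohortConfig, GroupParams, SyntheticCohort, generate_cohort, write_cohort

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]


def cohort_table_from_pairs(pairs, config: FeatureConfig = FeatureConfig()) -> CohortTable:
    """Extract features for (recording, covariates) pairs and assemble the
    model-ready cohort table; the AF label comes from ``af_label`` or, when
    absent, from the CASS subscore rule."""
    items = []
    for rec, cov in pairs:
        label = cov.af_label
        if label is None:
            label = af_diagnosis(CASSInput(cov.cardiovagal_score, cov.adrenergic_score))
        items.append((rec.patient_id, extract_features(rec, config), cov, label))
    return CohortTable.from_features(items)
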