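"""Two-class linear discriminant analysis, implemented from first principles.

For classes with shared covariance, the discriminant direction is
``w = S_pooled^{-1} (mu_pos - mu_neg)`` and a case is called positive when
``w . x > w . (mu_pos + mu_neg)/2 - log(pi_pos / pi_neg)`` — the Bayes rule
for two Gaussians with a common covariance matrix. The pooled covariance is
the df-weighted average of the within-class sample covariances; a ridge term
``lambda * trace(S)/p * I`` is added when the matrix is numerically singular
(exactly collinear features such as a derived mean arterial pressure).

Evaluation reports resubstitution (apparent) performance and, because a
single fit on the training data is optimistic, leave-one-out or k-fold
cross-validation with refitting per fold.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np

from .features import BINARY_FEATURES, FEATURE_COLUMNS, FeatureVector
from .io import PatientCovariates, ValidationError
from .stats_eval import (
    ConfusionCounts,
    DiagnosticReport,
    confusion_metrics,
    roc_analysis,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CohortTable",
    "LDAModel",
    "EvaluationResult",
    "fit_lda",
    "predict",
    "evaluate",
    "rank_single_features",
]

_COND_LIMIT = 1e10
_RIDGE_LAMBDA = 1e-6


@dataclass
class CohortTable:
    """Aligned per-patient features, autonomic-failure labels and covariates."""

    patient_ids: list[str]
    X: np.ndarray  # n x p, columns in column_order
    y: np.ndarray  # n bools
    covariates: list[Optional[PatientCovariates]]
    column_order: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=bool)
        n = len(self.patient_ids)
        if not (self.X.shape[0] == n == len(self.y) == len(self.covariates)):
            raise ValidationError("CohortTable fields have inconsistent length")
        if self.X.shape[1] != len(self.column_order):
            raise ValidationError("X width does not match column_order")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("CohortTable.X contains missing/non-finite cells")

    @classmethod
    def from_features(
        cls,
        items: Sequence[tuple[str, FeatureVector, Optional[PatientCovariates], bool]],
    ) -> "CohortTable":
        """Build from (patient_id, features, covariates, af_label) tuples."""
        return cls(
            patient_ids=[pid for pid, *_ in items],
            X=np.array([fv.to_array() for _, fv, *_ in items]),
            y=np.array([label for *_, label in items], dtype=bool),
            covariates=[cov for _, _, cov, _ in items],
        )

    def subset(self, idx: np.ndarray) -> "CohortTable":
        idx = np.asarray(idx)
        return CohortTable(
            [self.patient_ids[i] for i in idx],
            self.X[idx],
            self.y[idx],
            [self.covariates[i] for i in idx],
            list(self.column_order),
        )


@dataclass
class LDAModel:
    coefficients: np.ndarray  # p weights
    cutoff: float
    class_means: tuple[np.ndarray, np.ndarray]  # (mu_neg, mu_pos)
    pooled_covariance: np.ndarray
    priors: tuple[float, float]  # (pi_neg, pi_pos)
    column_order: list[str]
    ridge_applied: float = 0.0

    def to_json(self, path: Optional[str | Path] = None) -> str:
        payload = {
            "column_order": self.column_order,
            "coefficients": self.coefficients.tolist(),
            "cutoff": self.cutoff,
            "class_means": [m.tolist() for m in self.class_means],
            "pooled_covariance": self.pooled_covariance.tolist(),
            "priors": list(self.priors),
            "ridge_applied": self.ridge_applied,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LDAModel":
        text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            coefficients=np.array(d["coefficients"]),
            cutoff=float(d["cutoff"]),
            class_means=(np.array(d["class_means"][0]), np.array(d["class_means"][1])),
            pooled_covariance=np.array(d["pooled_covariance"]),
            priors=(d["priors"][0], d["priors"][1]),
            column_order=list(d["column_order"]),
            ridge_applied=float(d.get("ridge_applied", 0.0)),
        )


def _collinear_columns(S: np.ndarray, column_order: list[str]) -> list[str]:
    _, svals, vt = np.linalg.svd(S)
    tolerance = svals.max() * 1e-10 if svals.max() > 0 else 1.0
    names: list[str] = []
    for k in range(len(svals)):
        if svals[k] <= tolerance:
            involved = np.where(np.abs(vt[k]) > 0.1)[0]
            names.extend(column_order[j] for j in involved)
    return sorted(set(names))


def fit_lda(
    cohort: CohortTable,
    priors: Literal["empirical", "equal"] = "empirical",
    regularize: bool = True,
) -> LDAModel:
    """Fit the two-class linear discriminant.

    Empirical priors use the class frequencies (the clinical-prevalence
    reading); equal priors are available by flag. When the pooled covariance
    has condition number above 1e10 and ``regularize`` is on, an escalating
    ridge ``lambda * trace(S)/p`` (lambda from 1e-6, x10 steps) is added;
    with regularization off a singular matrix is an error naming the
    collinear columns.
    """
    X, y = cohort.X, cohort.y
    n, p = X.shape
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if n_pos < 2 or n_neg < 2:
        raise ValidationError(
            f"both classes need >= 2 members (got {n_neg} negative, {n_pos} positive)"
        )
    if p >= n:
        warnings.warn(f"p={p} >= n={n}: discriminant is poorly determined")
    mu_pos = X[y].mean(axis=0)
    mu_neg = X[~y].mean(axis=0)
    # within-class scatter normalised by n (not n-2): the discriminant
    # direction is identical up to scale, and this choice makes the fitted
    # model exactly invariant to duplicating every sample
    dev_pos = X[y] - mu_pos
    dev_neg = X[~y] - mu_neg
    S = (dev_pos.T @ dev_pos + dev_neg.T @ dev_neg) / n
    S = np.atleast_2d(S)

    ridge = 0.0
    S_reg = S
    lam = _RIDGE_LAMBDA
    while np.linalg.cond(S_reg) > _COND_LIMIT:
        if not regularize:
            raise ValidationError(
                "singular pooled covariance; collinear columns: "
                + ", ".join(_collinear_columns(S, cohort.column_order))
            )
        if lam > 1e-2:
            break
        ridge = lam * np.trace(S) / p
        S_reg = S + ridge * np.eye(p)
        lam *= 10.0
    if ridge:
        logger.info("ridge %.3g added to pooled covariance", ridge)

    w = np.linalg.solve(S_reg, mu_pos - mu_neg)
    if priors == "empirical":
        pi = (n_neg / n, n_pos / n)
    elif priors == "equal":
        pi = (0.5, 0.5)
    else:
        raise ValueError(f"unknown priors {priors!r}")
    cutoff = float(w @ (mu_pos + mu_neg) / 2.0 - np.log(pi[1] / pi[0]))
    return LDAModel(
        coefficients=w,
        cutoff=cutoff,
        class_means=(mu_neg, mu_pos),
        pooled_covariance=S_reg,
        priors=pi,
        column_order=list(cohort.column_order),
        ridge_applied=ridge,
    )


def predict(model: LDAModel, x: np.ndarray) -> tuple[float, bool]:
    """Discriminant score and label for one feature vector (ordered per
    ``model.column_order``); positive iff score strictly exceeds the cutoff."""
    x = np.asarray(x, dtype=float)
    if x.shape != model.coefficients.shape:
        raise ValidationError(
            f"dimension mismatch: x has {x.shape}, model expects {model.coefficients.shape}"
        )
    score = float(model.coefficients @ x)
    return score, score > model.cutoff


def _predict_many(model: LDAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = X @ model.coefficients
    return scores, scores > model.cutoff


@dataclass
class EvaluationResult:
    report: DiagnosticReport
    scheme: str
    scores: np.ndarray
    predicted: np.ndarray


def _counts(y: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        tp=int((pred & y).sum()),
        fp=int((pred & ~y).sum()),
        fn=int((~pred & y).sum()),
        tn=int((~pred & ~y).sum()),
    )


def evaluate(
    cohort: CohortTable,
    scheme: Literal["resubstitution", "loocv", "kfold"] = "resubstitution",
    priors: Literal["empirical", "equal"] = "empirical",
    model: Optional[LDAModel] = None,
    k: int = 5,
    seed: int = 0,
    regularize: bool = True,
) -> EvaluationResult:
    """Confusion-matrix evaluation under resubstitution or cross-validation.

    Cross-validation refits per fold and is deterministic given ``seed``;
    a fold whose training part lacks a class is merged into the next fold
    with a warning.
    """
    y = cohort.y
    n = len(y)
    if scheme == "resubstitution":
        m = model if model is not None else fit_lda(cohort, priors, regularize)
        scores, pred = _predict_many(m, cohort.X)
    elif scheme in ("loocv", "kfold"):
        if scheme == "loocv":
            folds = [np.array([i]) for i in range(n)]
        else:
            rng = np.random.default_rng(seed)
            perm = rng.permutation(n)
            folds = [perm[i::k] for i in range(k)]
        merged: list[np.ndarray] = []
        pending = np.array([], dtype=int)
        for f in folds:
            f = np.concatenate([pending, f])
            train_mask = np.ones(n, dtype=bool)
            train_mask[f] = False
            if y[train_mask].all() or not y[train_mask].any():
                warnings.warn("fold leaves single-class training set; merging with next fold")
                pending = f
                continue
            merged.append(f)
            pending = np.array([], dtype=int)
        if len(pending):
            if not merged:
                raise ValidationError("cross-validation impossible: single-class data")
            merged[-1] = np.concatenate([merged[-1], pending])
        scores = np.empty(n)
        pred = np.empty(n, dtype=bool)
        for f in merged:
            train_mask = np.ones(n, dtype=bool)
            train_mask[f] = False
            m = fit_lda(cohort.subset(np.where(train_mask)[0]), priors, regularize)
            scores[f], pred[f] = _predict_many(m, cohort.X[f])
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return EvaluationResult(
        report=confusion_metrics(_counts(y, pred)),
        scheme=scheme,
        scores=scores,
        predicted=pred,
    )


def rank_single_features(cohort: CohortTable) -> list[dict]:
    """Diagnostic accuracy of each ABPM parameter taken alone.

    Binary parameters are used directly as the test; continuous parameters
    are dichotomised at their Youden-optimal ROC cut-point (direction chosen
    to give AUC >= 0.5). Returns one dict per feature with accuracy,
    sensitivity, specificity, AUC and the cut-point used, sorted by
    decreasing accuracy.
    """
    y = cohort.y
    rows: list[dict] = []
    for j, name in enumerate(cohort.column_order):
        x = cohort.X[:, j]
        if name in BINARY_FEATURES:
            pred = x > 0.5
            auc = None
            cutoff = None
        else:
            if np.ptp(x) == 0:
                continue
            roc_hi = roc_analysis(x, y, "higher")
            roc_lo = roc_analysis(x, y, "lower")
            roc = roc_hi if roc_hi.auc >= roc_lo.auc else roc_lo
            auc = roc.auc
            cutoff = roc.youden_cutoff
            pred = x >= cutoff if roc.positive_direction == "higher" else x <= cutoff
        report = confusion_metrics(_counts(y, pred))
        rows.append(
            {
                "feature": name,
                "accuracy": report.accuracy.value,
                "sensitivity": report.sensitivity.value,
                "specificity": report.specificity.value,
                "auc": auc,
                "cutoff": cutoff,
            }
        )
    rows.sort(key=lambda r: -r["accuracy"])
    return rows
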