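"""Diagnostic-accuracy statistics for binary screening tests.

Contingency (2x2) metrics with exact Clopper-Pearson confidence intervals,
empirical ROC analysis with the Youden-index cut-point and a Hanley-McNeil
AUC interval, cross-product odds ratios with Woolf intervals, logistic
regression (delegated to statsmodels' IRLS fitter) and two-group
comparisons. Point estimates are proportions in [0, 1]; display-rounding
helpers reproduce the clinical-report convention (integer percent, two
significant figures for odds ratios).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

__all__ = [
    "ConfusionCounts",
    "MetricCI",
    "DiagnosticReport",
    "ROCResult",
    "PredictorEffect",
    "LogisticResult",
    "confusion_metrics",
    "proportion_ci",
    "roc_analysis",
    "odds_ratio_2x2",
    "logistic_fit",
    "group_compare",
    "round_percent",
    "round_sigfigs",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts. As a diagnostic table: tp/fp/fn/tn against the reference
    diagnosis. As an exposure table (odds ratios): a=tp exposed cases,
    b=fn unexposed cases, c=fp exposed controls, d=tn unexposed controls."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.n == 0:
            raise ValidationError("empty 2x2 table")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricCI:
    """A proportion with its two-sided CI; ``defined`` is False when the
    denominator was zero (value/CI then NaN, never silently 0)."""

    value: float
    lo: float
    hi: float
    defined: bool = True

    def as_percent(self) -> tuple[int, int, int]:
        return round_percent(self.value), round_percent(self.lo), round_percent(self.hi)


@dataclass(frozen=True)
class DiagnosticReport:
    accuracy: MetricCI
    sensitivity: MetricCI
    specificity: MetricCI
    ppv: MetricCI
    npv: MetricCI
    counts: ConfusionCounts


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    youden_cutoff: float
    youden_value: float
    positive_direction: str


@dataclass(frozen=True)
class PredictorEffect:
    name: str
    odds_ratio: float
    ci: tuple[float, float]
    p_value: float
    coefficient: float


@dataclass(frozen=True)
class LogisticResult:
    effects: list[PredictorEffect]
    adjusted: bool
    separation_flag: bool
    converged: bool
    names: list[str] = field(default_factory=list)

    def effect(self, name: str) -> PredictorEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


# ---------------------------------------------------------------------------
# rounding conventions for report display


def round_percent(p: float) -> int:
    """Proportion -> integer percent, half away from zero.

    A relative epsilon keeps exact halves (e.g. 17/40) on the away-from-zero
    side despite binary float representation.
    """
    return int(math.floor(abs(p) * 100.0 + 0.5 + 1e-9)) * (1 if p >= 0 else -1)


def round_sigfigs(x: float, sig: int = 2) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    d = math.ceil(math.log10(abs(x)))
    return round(x, sig - d)


# ---------------------------------------------------------------------------


def proportion_ci(
    k: int,
    n: int,
    level: float = 0.95,
    method: Literal["clopper-pearson", "wilson"] = "clopper-pearson",
) -> tuple[float, float]:
    """Two-sided CI for a binomial proportion.

    Default is the exact Clopper-Pearson interval from beta quantiles
    (lower bound exactly 0 when k=0, upper exactly 1 when k=n); Wilson's
    score interval is available by flag.
    """
    if not (0 <= k <= n) or n <= 0:
        raise ValidationError(f"invalid proportion counts k={k}, n={n}")
    alpha = 1.0 - level
    if method == "clopper-pearson":
        lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
        hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
        return lo, hi
    if method == "wilson":
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
        return float(lo), float(hi)
    raise ValueError(f"unknown CI method {method!r}")


def _metric(k: int, n: int, level: float, method: str) -> MetricCI:
    if n == 0:
        return MetricCI(math.nan, math.nan, math.nan, defined=False)
    lo, hi = proportion_ci(k, n, level, method)  # type: ignore[arg-type]
    return MetricCI(k / n, lo, hi)


def confusion_metrics(
    counts: ConfusionCounts,
    level: float = 0.95,
    ci_method: Literal["clopper-pearson", "wilson"] = "clopper-pearson",
) -> DiagnosticReport:
    """Accuracy, sensitivity, specificity, PPV and NPV with binomial CIs."""
    c = counts
    return DiagnosticReport(
        accuracy=_metric(c.tp + c.tn, c.n, level, ci_method),
        sensitivity=_metric(c.tp, c.tp + c.fn, level, ci_method),
        specificity=_metric(c.tn, c.tn + c.fp, level, ci_method),
        ppv=_metric(c.tp, c.tp + c.fp, level, ci_method),
        npv=_metric(c.tn, c.tn + c.fn, level, ci_method),
        counts=c,
    )


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[bool],
    positive_direction: Literal["higher", "lower"] = "higher",
    level: float = 0.95,
) -> ROCResult:
    """Empirical ROC over the unique observed thresholds.

    A case is called positive when its score is >= threshold ("higher"
    direction) or <= threshold ("lower"). AUC is the trapezoidal area, which
    equals the tie-corrected Mann-Whitney concordance; its CI uses the
    Hanley-McNeil variance. The Youden cut-point maximises sens + spec - 1,
    ties broken toward the lower threshold (the more sensitive test under
    the "higher" direction).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D")
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("ROC requires both classes present")
    sign = 1.0 if positive_direction == "higher" else -1.0
    sv = sign * s
    thresholds = np.unique(sv)
    sens = np.array([(sv[y] >= t).mean() for t in thresholds])
    spec = np.array([(sv[~y] < t).mean() for t in thresholds])
    # trapezoid along the threshold path (anchored at (1,1) and (0,0));
    # integrating in threshold order keeps simultaneous sens/spec jumps at
    # tied scores on the diagonal, which is the half-credit tie convention
    fpr = np.concatenate([[1.0], 1.0 - spec, [0.0]])
    tpr = np.concatenate([[1.0], sens, [0.0]])
    auc = float(np.sum((fpr[:-1] - fpr[1:]) * (tpr[:-1] + tpr[1:]) / 2.0))

    j = sens + spec - 1.0
    best = int(np.argmax(j == j.max()))  # first (lowest) threshold at the max
    youden_cutoff = float(sign * thresholds[best])

    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (
        n1 * n0
    )
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return ROCResult(
        thresholds=sign * thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        auc_ci=(max(0.0, auc - half), min(1.0, auc + half)),
        youden_cutoff=youden_cutoff,
        youden_value=float(j[best]),
        positive_direction=positive_direction,
    )


def odds_ratio_2x2(
    counts: ConfusionCounts, level: float = 0.95
) -> tuple[float, tuple[float, float], float]:
    """Cross-product odds ratio with Woolf (log-scale Wald) CI and p-value.

    On the exposure reading of the table, OR = (a*d)/(b*c). Zero cells get
    the Haldane-Anscombe 0.5 correction (applied to all four cells, with a
    warning). Returns (or, (lo, hi), p).
    """
    a, b, c, d = counts.tp, counts.fn, counts.fp, counts.tn
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValidationError("odds ratio undefined: empty table margin")
    if 0 in (a, b, c, d):
        warnings.warn("zero cell: applying Haldane-Anscombe 0.5 correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se)
    p = 2.0 * stats.norm.sf(abs(math.log(or_)) / se)
    return or_, (lo, hi), float(p)


_SEPARATION_COEF = 15.0  # |log-odds| beyond which a predictor is effectively separating


def _safe_exp(v: float) -> float:
    return math.exp(v) if v < 700.0 else math.inf


def logistic_fit(
    X: np.ndarray,
    y: Sequence[bool],
    names: Optional[list[str]] = None,
    adjusted: bool = False,
    max_iter: int = 100,
    tol: float = 1e-8,
    level: float = 0.95,
) -> LogisticResult:
    """Maximum-likelihood logistic regression (IRLS) with Wald CIs.

    An intercept is added; per-predictor odds ratios are exp(coefficient).
    Quasi-complete separation (diverging coefficient) is flagged rather than
    raised, so the caller can still see the direction of the association.
    """
    import statsmodels.api as sm

    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(y) == X.shape[1]:
        X = X.T
    yv = np.asarray(y, dtype=float)
    n, q = X.shape
    if names is None:
        names = [f"x{j + 1}" for j in range(q)]
    if len(names) != q:
        raise ValidationError("names length does not match number of predictors")
    if n <= q:
        raise ValidationError(f"n={n} must exceed number of predictors q={q}")
    for j in range(q):
        if np.ptp(X[:, j]) == 0:
            raise ValidationError(f"predictor {names[j]!r} has zero variance")
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.GLM(yv, Xc, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=max_iter, tol=tol)
    converged = bool(getattr(res, "converged", True))
    if not converged and not np.any(np.abs(res.params[1:]) > _SEPARATION_COEF):
        raise ValidationError(f"logistic regression did not converge in {max_iter} iterations")
    z = stats.norm.ppf(0.5 + level / 2.0)
    effects = []
    separation = False
    for j in range(q):
        beta = float(res.params[j + 1])
        se = float(res.bse[j + 1])
        if abs(beta) > _SEPARATION_COEF or not math.isfinite(se):
            separation = True
        effects.append(
            PredictorEffect(
                name=names[j],
                odds_ratio=_safe_exp(beta),
                ci=(_safe_exp(beta - z * se), _safe_exp(beta + z * se)),
                p_value=float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else math.nan,
                coefficient=beta,
            )
        )
    return LogisticResult(
        effects=effects,
        adjusted=adjusted,
        separation_flag=separation,
        converged=converged,
        names=list(names),
    )


def group_compare(
    group_a,
    group_b,
    kind: Literal["continuous", "categorical"] = "continuous",
    normal: Optional[bool] = None,
) -> tuple[float, str]:
    """Two-group comparison, returning (p_value, test_name).

    Continuous: Student's t-test when both samples look normal (Shapiro-Wilk
    at 0.05, or ``normal=True``), otherwise Mann-Whitney. Categorical:
    ``group_a``/``group_b`` are (count_with, count_without) tuples; chi-square
    unless any expected cell is <= 5, then Fisher's exact test.
    """
    if kind == "continuous":
        a = np.asarray(group_a, dtype=float)
        b = np.asarray(group_b, dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValidationError("empty group")
        if normal is None:
            try:
                normal = (
                    stats.shapiro(a).pvalue > 0.05 and stats.shapiro(b).pvalue > 0.05
                )
            except ValueError:
                normal = False
        if normal:
            p = stats.ttest_ind(a, b, equal_var=True).pvalue
            return float(p), "t-test"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        return float(p), "mann-whitney"
    if kind == "categorical":
        table = np.array([list(group_a), list(group_b)], dtype=float)
        if table.sum(axis=1).min() == 0:
            raise ValidationError("empty group")
        expected = stats.contingency.expected_freq(table)
        if (expected <= 5).any():
            p = stats.fisher_exact(table)[1]
            return float(p), "fisher"
        p = stats.chi2_contingency(table, correction=False)[1]
        return float(p), "chi-square"
    raise ValueError(f"unknown kind {kind!r}")


def report_row(name: str, report: DiagnosticReport, auc: Optional[float] = None) -> dict:
    """Flatten a DiagnosticReport into one machine-readable table row."""
    row: dict = {"parameter": name, "n": report.counts.n, "auc": auc}
    for metric in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
        m: MetricCI = getattr(report, metric)
        row[metric] = m.value
        row[f"{metric}_lo"] = m.lo
        row[f"{metric}_hi"] = m.hi
    return row
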