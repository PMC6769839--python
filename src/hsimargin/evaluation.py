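"""ROC/AUC evaluation, operating points, distance-stratified reports,
paired modality comparisons, and specimen-type confusion metrics.

AUC of the ROC is the primary metric: it summarizes accuracy over all score
thresholds and is robust to class imbalance. Hard metrics (accuracy,
sensitivity, specificity) are computed at an operating point chosen on
validation data only — the Youden-optimal validation threshold is applied
unchanged to the test data — so test labels never inform the threshold.

Sensitivity and specificity follow the standard definitions
(``TP/(TP+FN)`` and ``TN/(TN+FP)``); PPV and NPV are reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .hypercube_io import TUMOR, ConfigurationError
from .margin_geometry import DistanceMap, exclusion_mask

__all__ = [
    "PredictionMap",
    "ROCCurve",
    "OperatingPoint",
    "ThresholdMetrics",
    "PairedTestResult",
    "SpecimenConfusion",
    "EvalCase",
    "roc_auc",
    "optimal_operating_point",
    "metrics_at_threshold",
    "distance_report",
    "aggregate_distance_report",
    "paired_one_tailed_ttest",
    "specimen_confusion",
]


@dataclass
class PredictionMap:
    """Per-pixel cancer probability reconstructed from a classifier."""

    values: np.ndarray  # H x W in [0, 1]; NaN where invalid
    valid: np.ndarray  # boolean H x W


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class OperatingPoint:
    threshold: float
    source: str = "validation"
    youden_j: float = float("nan")


@dataclass
class ThresholdMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve and trapezoidal AUC.

    Tied scores cross their threshold simultaneously, so ties contribute the
    half-credit diagonal segment; the trapezoidal area then equals the
    Mann-Whitney statistic (concordant pairs + half the ties). Constant
    scores give AUC 0.5 (random guess).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ConfigurationError("AUC undefined: both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    # sklearn reports +inf for the all-negative threshold; clamp to a usable cut
    thr = np.where(np.isinf(thr), scores.max() + 1.0, thr)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def optimal_operating_point(
    roc: ROCCurve, *, method: str = "youden", source: str = "validation"
) -> OperatingPoint:
    """Score threshold at the optimal point of a (validation) ROC curve.

    Default criterion is Youden's J = TPR - FPR; ties are broken toward
    higher specificity (lower FPR), then toward the higher threshold. The
    alternative ``method="closest"`` picks the point nearest (0, 1).
    """
    if method == "youden":
        objective = roc.tpr - roc.fpr
    elif method == "closest":
        objective = -np.hypot(roc.fpr, 1.0 - roc.tpr)
    else:
        raise ConfigurationError(f"unknown operating-point method {method!r}")
    best = objective.max()
    candidates = np.nonzero(objective >= best - 1e-12)[0]
    # lower fpr = higher specificity; among those, the larger threshold
    order = sorted(candidates, key=lambda i: (roc.fpr[i], -roc.thresholds[i]))
    i = order[0]
    return OperatingPoint(
        threshold=float(roc.thresholds[i]), source=source,
        youden_j=float(roc.tpr[i] - roc.fpr[i]),
    )


def metrics_at_threshold(
    scores, labels, threshold: float
) -> ThresholdMetrics:
    """Confusion-matrix metrics with predictions ``score >= threshold``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.size == 0:
        warnings.warn("empty evaluation set: metrics undefined", stacklevel=2)
        nan = float("nan")
        return ThresholdMetrics(nan, nan, nan, nan, nan, 0, 0, 0, 0)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))

    def _ratio(a, b):
        return a / b if b > 0 else float("nan")

    return ThresholdMetrics(
        accuracy=_ratio(tp + tn, tp + fp + tn + fn),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


# ---------------------------------------------------------------------------
# Distance-stratified reporting
# ---------------------------------------------------------------------------


@dataclass
class EvalCase:
    """One specimen's aligned prediction, truth, and margin geometry."""

    patient_id: str
    modality: str
    predmap: PredictionMap
    gt_mask: np.ndarray
    distmap: DistanceMap
    tissue_eval: np.ndarray  # trimmed tissue pixels eligible for evaluation
    threshold: float  # validation-derived operating point


def _case_metrics(case: EvalCase, d_mm: float, semantics: str) -> dict:
    if case.predmap.values.shape != case.gt_mask.shape:
        raise ConfigurationError("prediction and truth rasters are misaligned")
    ev = exclusion_mask(case.distmap, d_mm, case.tissue_eval, semantics=semantics)
    sel = ev.included & case.predmap.valid & np.isfinite(case.predmap.values)
    labels = (case.gt_mask[sel] == TUMOR).astype(int)
    scores = case.predmap.values[sel]
    n = int(sel.sum())
    attainable = n > 0 and 0 < labels.sum() < n
    row = {
        "patient_id": case.patient_id,
        "modality": case.modality,
        "d_mm": float(d_mm),
        "n_pixels": n,
        "attainable": attainable,
        "auc": float("nan"),
        "accuracy": float("nan"),
        "sensitivity": float("nan"),
        "specificity": float("nan"),
    }
    if attainable:
        row["auc"] = roc_auc(scores, labels).auc
        m = metrics_at_threshold(scores, labels, case.threshold)
        row.update(
            accuracy=m.accuracy, sensitivity=m.sensitivity, specificity=m.specificity
        )
    return row


DEFAULT_D_GRID_MM = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


def distance_report(
    cases: list[EvalCase],
    d_grid_mm=DEFAULT_D_GRID_MM,
    *,
    semantics: str = "exclude_within",
) -> pd.DataFrame:
    """Per-(patient, modality, d) metrics over the margin-distance grid.

    At each distance ``d`` the pixels within ``d`` mm of the tumor-normal
    interface are removed before computing AUC and threshold metrics.
    Specimens for which a given ``d`` leaves no pixels of one class are
    marked unattainable at that ``d`` and excluded from aggregates — not all
    distances can be estimated from every specimen.
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-mask warnings become 'unattainable'
        for case in cases:
            for d in d_grid_mm:
                rows.append(_case_metrics(case, d, semantics))
    return pd.DataFrame(rows)


def aggregate_distance_report(report: pd.DataFrame) -> pd.DataFrame:
    """Median/mean/SEM of per-patient AUC and accuracy at each distance."""
    ok = report[report["attainable"]]
    grouped = ok.groupby(["modality", "d_mm"])
    agg = grouped.agg(
        n_patients=("patient_id", "nunique"),
        median_auc=("auc", "median"),
        mean_auc=("auc", "mean"),
        sem_auc=("auc", "sem"),
        median_accuracy=("accuracy", "median"),
        mean_accuracy=("accuracy", "mean"),
    )
    return agg.reset_index()


# ---------------------------------------------------------------------------
# Paired modality comparison
# ---------------------------------------------------------------------------


@dataclass
class PairedTestResult:
    t_statistic: float
    p_one_tailed: float
    n_pairs: int
    direction: str  # 'greater': H1 is mean(a - b) > 0
    mean_difference: float
    degenerate: bool = False


def paired_one_tailed_ttest(
    metric_a, metric_b, direction: str = "greater"
) -> PairedTestResult:
    """Paired one-tailed t-test on per-patient metric values.

    Pairs with a missing value on either side are dropped (a patient must
    have both modalities at the given distance to contribute). With
    ``direction='greater'`` the alternative is mean(a - b) > 0.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("paired samples must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    diff = a[keep] - b[keep]
    n = len(diff)
    if n < 2:
        raise ConfigurationError(f"need >= 2 complete pairs, got {n}")
    if direction not in ("greater", "less"):
        raise ConfigurationError("direction must be 'greater' or 'less'")
    mean = diff.mean()
    sd = diff.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if mean == 0 else np.inf * np.sign(mean)
        p = 0.5 if mean == 0 else (0.0 if (mean > 0) == (direction == "greater") else 1.0)
        warnings.warn("zero-variance paired differences: p-value degenerate",
                      stacklevel=2)
        return PairedTestResult(float(t), float(p), n, direction, float(mean), True)
    t = mean / (sd / np.sqrt(n))
    if direction == "greater":
        p = float(stats.t.sf(t, df=n - 1))
    else:
        p = float(stats.t.cdf(t, df=n - 1))
    return PairedTestResult(float(t), p, n, direction, float(mean), False)


# ---------------------------------------------------------------------------
# Specimen-type confusion (T / TN / N identification)
# ---------------------------------------------------------------------------


@dataclass
class SpecimenConfusion:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


_COMPONENTS = {"T": ("T",), "N": ("N",), "TN": ("T", "N")}


def specimen_confusion(true_types, predicted_types) -> SpecimenConfusion:
    """Confusion metrics for specimen-type (T/TN/N) identification.

    Margin specimens are decomposed into their tumor and normal components on
    both the truth and prediction side. Matching components pair directly
    (T with T is a true positive, N with N a true negative); an unmatched
    component pairs with the opposite side's single component, so a true TN
    predicted as all T counts as a true positive plus a false positive, and a
    true T predicted as TN counts as a true positive plus a false negative.
    """
    tp = fp = tn = fn = 0
    for truth, pred in zip(true_types, predicted_types, strict=True):
        if truth not in _COMPONENTS or pred not in _COMPONENTS:
            raise ConfigurationError(
                f"specimen types must be T, N, or TN; got {truth!r} / {pred!r}"
            )
        ct = set(_COMPONENTS[truth])
        cp = set(_COMPONENTS[pred])
        matched = ct & cp
        for c in matched:
            if c == "T":
                tp += 1
            else:
                tn += 1
        if not matched:
            # singleton mismatch (T predicted N, or N predicted T): one pair
            if truth == "T":
                fn += 1
            else:
                fp += 1
            continue
        for c in ct - cp:  # true component predicted as the other class
            if c == "T":
                fn += 1
            else:
                fp += 1
        for c in cp - ct:  # predicted component with no matching truth
            if c == "T":
                fp += 1
            else:
                fn += 1

    def _ratio(x, y):
        return x / y if y > 0 else float("nan")

    total = tp + fp + tn + fn
    return SpecimenConfusion(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=_ratio(tp + tn, total),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )
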