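"""Patient-level diagnosis aggregation and screening metrics.

A patient is called positive as soon as *any* frame in *either* view of the
biplane sequence carries a retained aneurysm detection — a deliberately
strict OR designed for high sensitivity.  The patient's *disease
confidence* is the maximum aneurysm confidence across the whole sequence,
which feeds the ROC analysis.

Confusion-matrix counts may be fractional so that cross-validation-averaged
matrices (e.g. 19.2 true positives averaged over five folds) are
representable verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .core_types import Detection, Label, View

__all__ = [
    "ConfusionMatrix",
    "PatientEvaluation",
    "UndefinedMetricError",
    "aggregate_patient",
    "confusion",
    "metrics",
    "roc_auc",
    "threshold_distribution",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero; the value is undefined, not 0."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 diagnosis counts; fractional values allowed (fold averages)."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PatientEvaluation:
    patient_id: str
    diag_predicted: bool
    disease_confidence: float
    truth: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.disease_confidence <= 1.0:
            raise ValueError("disease_confidence must be in [0,1]")


def aggregate_patient(
    patient_id: str,
    detections: Mapping[int, Mapping[View, Sequence[Detection]]],
    truth: bool,
) -> PatientEvaluation:
    """OR-over-frames diagnosis and max-confidence aggregation.

    ``detections`` maps frame index -> view -> retained detections (already
    past the confidence-retention step and, if enabled, suppression).  Only
    aneurysm-labeled detections count toward the diagnosis; a patient with
    no frames is an error.
    """
    if not detections:
        raise ValueError("patient has no frames to aggregate")
    best = 0.0
    any_positive = False
    for per_view in detections.values():
        for dets in per_view.values():
            for d in dets:
                if d.label is Label.ANEURYSM:
                    any_positive = True
                    best = max(best, d.confidence)
    return PatientEvaluation(
        patient_id=patient_id,
        diag_predicted=any_positive,
        disease_confidence=best,
        truth=truth,
    )


def confusion(evaluations: Iterable[PatientEvaluation]) -> ConfusionMatrix:
    tp = fp = tn = fn = 0.0
    for ev in evaluations:
        if ev.diag_predicted and ev.truth:
            tp += 1
        elif ev.diag_predicted and not ev.truth:
            fp += 1
        elif not ev.diag_predicted and ev.truth:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy).

    sensitivity = TP/(TP+FN); specificity = TN/(FP+TN);
    accuracy = (TP+TN)/total.  A zero denominator raises
    :class:`UndefinedMetricError` rather than silently returning 0.
    """
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("no positive patients: sensitivity undefined")
    if cm.fp + cm.tn == 0:
        raise UndefinedMetricError("no negative patients: specificity undefined")
    if cm.total == 0:
        raise UndefinedMetricError("empty cohort: accuracy undefined")
    sensitivity = cm.tp / (cm.tp + cm.fn)
    specificity = cm.tn / (cm.fp + cm.tn)
    accuracy = (cm.tp + cm.tn) / cm.total
    return sensitivity, specificity, accuracy


def roc_auc(
    evaluations: Sequence[PatientEvaluation],
) -> tuple[list[tuple[float, float]], float]:
    """ROC over disease confidence and its trapezoidal AUC.

    Thresholds are the observed confidence values (equal confidences are
    grouped into a single step).  Requires at least one positive and one
    negative patient.
    """
    y = np.array([ev.truth for ev in evaluations], dtype=int)
    s = np.array([ev.disease_confidence for ev in evaluations], dtype=float)
    if y.size == 0 or y.min() == y.max():
        raise ValueError("ROC requires at least one positive and one negative")
    fpr, tpr, _ = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def threshold_distribution(
    evaluations: Sequence[PatientEvaluation], c_grid: Sequence[float]
) -> list[tuple[float, int, int]]:
    """Per threshold c: (c, #patients with confidence >= c, #with < c).

    The two counts always sum to the cohort size; the distribution guides
    the manual choice of the suppression gate c.
    """
    out = []
    for c in c_grid:
        ge = sum(1 for ev in evaluations if ev.disease_confidence >= c)
        out.append((float(c), ge, len(evaluations) - ge))
    return out
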