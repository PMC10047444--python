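"""Confusion-matrix evaluation and inter-annotator agreement.

Implements the closed-form performance measures used to validate both the
extractor and the change classifier against manual review: sensitivity
(recall), specificity, precision / PPV, NPV, accuracy, F1 and the Matthews
correlation coefficient, plus Cohen's kappa for annotator agreement.
Zero-denominator metrics are reported as explicit ``None``, never silently
zeroed and never a crash.  Multiclass label lists (e.g. the three cohorts)
are evaluated one-vs-rest and macro-averaged.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Optional, Sequence


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Derived performance measures; None marks a zero-denominator metric."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]
    f1: Optional[float]
    mcc: Optional[float]

    @property
    def ppv(self) -> Optional[float]:
        return self.precision

    @property
    def recall(self) -> Optional[float]:
        return self.sensitivity

    def as_dict(self) -> dict[str, Optional[float]]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "mcc": self.mcc,
        }


def confusion(
    gold: Sequence[Hashable], pred: Sequence[Hashable], positive_class: Hashable
) -> ConfusionMatrix:
    """One-vs-rest confusion counts for the given positive class."""
    if len(gold) != len(pred):
        raise ValueError(f"gold ({len(gold)}) and pred ({len(pred)}) lengths differ")
    if not gold:
        raise ValueError("cannot build a confusion matrix from empty label lists")
    tp = fp = tn = fn = 0
    for g, p in zip(gold, pred):
        g_pos = g == positive_class
        p_pos = p == positive_class
        if g_pos and p_pos:
            tp += 1
        elif not g_pos and p_pos:
            fp += 1
        elif g_pos and not p_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fp, tn, fn)


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den else None


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Closed-form metrics from the four cells.

    precision = tp/(tp+fp); sensitivity = tp/(tp+fn); specificity =
    tn/(tn+fp); npv = tn/(tn+fn); accuracy = (tp+tn)/total; F1 is the
    harmonic mean of precision and recall; MCC = (tp*tn - fp*fn) /
    sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)).
    """
    if cm.total == 0:
        raise ValueError("all-zero confusion matrix")
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    precision = _ratio(tp, tp + fp)
    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    npv = _ratio(tn, tn + fn)
    accuracy = (tp + tn) / cm.total
    if precision is None or sensitivity is None or (precision + sensitivity) == 0:
        f1 = None
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else None
    return MetricsReport(sensitivity, specificity, precision, npv, accuracy, f1, mcc)


def macro_metrics(
    gold: Sequence[Hashable], pred: Sequence[Hashable]
) -> tuple[dict[Hashable, MetricsReport], dict[str, Optional[float]]]:
    """Per-class one-vs-rest reports plus their macro (unweighted) average.

    Classes are the union of labels observed in either list; metrics that are
    undefined for a class are left out of that metric's average (all-undefined
    gives None).
    """
    classes = sorted(set(gold) | set(pred), key=str)
    per_class = {c: metrics(confusion(gold, pred, c)) for c in classes}
    macro: dict[str, Optional[float]] = {}
    for key in ("sensitivity", "specificity", "precision", "npv", "accuracy", "f1", "mcc"):
        vals = [getattr(r, key) for r in per_class.values() if getattr(r, key) is not None]
        macro[key] = sum(vals) / len(vals) if vals else None
    return per_class, macro


def cohens_kappa(ann1: Sequence[Hashable], ann2: Sequence[Hashable]) -> float:
    """Chance-corrected agreement between two annotators.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e computed from
    the two annotators' marginal label frequencies.  The degenerate case where
    both annotators use a single identical label (p_e = p_o = 1) is perfect
    agreement, kappa = 1.
    """
    if len(ann1) != len(ann2):
        raise ValueError("annotator label lists must have equal length")
    if not ann1:
        raise ValueError("annotator label lists must be non-empty")
    n = len(ann1)
    po = sum(a == b for a, b in zip(ann1, ann2)) / n
    m1, m2 = Counter(ann1), Counter(ann2)
    pe = sum(m1[lab] * m2.get(lab, 0) for lab in m1) / (n * n)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)
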