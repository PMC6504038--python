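"""Confusion-matrix evaluation: per-class metrics, accuracy, MF1, Cohen's κ.

Everything is computed from a single C×C integer confusion matrix with
reference stages on the rows and predicted stages on the columns, in the
order W, N1, N2, N3, REM. For class c,

    TP = cm[c, c]          FP = column sum − TP
    FN = row sum − TP      TN = total − TP − FP − FN

    precision   = TP/(TP+FP)        recall = TP/(TP+FN)
    specificity = TN/(TN+FP)        F1 = 2·P·R/(P+R)

Overall accuracy is trace/total; MF1 is the unweighted mean of per-class
F1; κ = (p_o − p_e)/(1 − p_e) with p_o the observed and p_e the chance
agreement. Percentages are reported rounded to two decimals. A metric with
a zero denominator is reported as 0 and flagged as degenerate rather than
propagating NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .stages import N_STAGES, STAGE_NAMES


@dataclass
class ConfusionMatrix:
    """C×C integer counts, reference rows × predicted columns."""

    counts: np.ndarray
    class_names: tuple[str, ...] = STAGE_NAMES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        c = len(self.class_names)
        if self.counts.shape != (c, c):
            raise ValueError(f"expected a {c}x{c} matrix, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts, self.class_names)


@dataclass
class ClassMetrics:
    """One stage's TP/TN/FP/FN tallies and derived percentages."""

    tp: int
    tn: int
    fp: int
    fn: int
    precision: float
    recall: float
    specificity: float
    f1: float
    degenerate: bool = False


@dataclass
class MetricsReport:
    """The full evaluation summary for one pooled confusion matrix."""

    per_class: dict[str, ClassMetrics]
    accuracy: float
    macro_f1: float
    kappa: float
    confusion: ConfusionMatrix = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "kappa": self.kappa,
            "per_class": {
                name: {
                    "precision": m.precision,
                    "recall": m.recall,
                    "specificity": m.specificity,
                    "f1": m.f1,
                    "tp": m.tp, "tn": m.tn, "fp": m.fp, "fn": m.fn,
                }
                for name, m in self.per_class.items()
            },
            "confusion": self.confusion.counts.tolist() if self.confusion else None,
        }


def confusion(y_true, y_pred, n_classes: int = N_STAGES,
              class_names: tuple[str, ...] | None = None) -> ConfusionMatrix:
    """Tally a confusion matrix from parallel label lists."""
    y_true = np.asarray([int(v) for v in y_true])
    y_pred = np.asarray([int(v) for v in y_pred])
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        bad = (arr < 0) | (arr >= n_classes)
        if bad.any():
            raise ValueError(f"{name} contains labels outside 0..{n_classes - 1}")
    counts = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))
    names = class_names or (STAGE_NAMES if n_classes == N_STAGES
                            else tuple(f"C{i}" for i in range(n_classes)))
    return ConfusionMatrix(counts, names)


def _safe_ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def per_class_metrics(cm: ConfusionMatrix) -> dict[str, ClassMetrics]:
    """Per-stage precision/recall/specificity/F1 (percent, 2 decimals)."""
    counts = cm.counts
    total = cm.total
    out: dict[str, ClassMetrics] = {}
    for c, name in enumerate(cm.class_names):
        tp = int(counts[c, c])
        fp = int(counts[:, c].sum() - tp)
        fn = int(counts[c, :].sum() - tp)
        tn = total - tp - fp - fn
        prec, d1 = _safe_ratio(tp, tp + fp)
        rec, d2 = _safe_ratio(tp, tp + fn)
        spec, d3 = _safe_ratio(tn, tn + fp)
        f1, d4 = _safe_ratio(2 * prec * rec, prec + rec)
        out[name] = ClassMetrics(
            tp=tp, tn=tn, fp=fp, fn=fn,
            precision=round(prec * 100, 2),
            recall=round(rec * 100, 2),
            specificity=round(spec * 100, 2),
            f1=round(f1 * 100, 2),
            degenerate=d1 or d2 or d3 or d4,
        )
    return out


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """trace/total as a percent, 2 decimals."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return round(np.trace(cm.counts) / cm.total * 100, 2)


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean of the per-class F1 percentages."""
    per = per_class_metrics(cm)
    return round(float(np.mean([m.f1 for m in per.values()])), 2)


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement κ = (p_o − p_e)/(1 − p_e).

    For the degenerate single-class matrix (p_e = 1), κ is 1 when the
    observed agreement is also perfect and 0 otherwise.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm.counts) / total
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    p_e = float((row * col).sum()) / total**2
    if abs(1.0 - p_e) < 1e-12:
        return 1.0 if abs(1.0 - p_o) < 1e-12 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def report(cm: ConfusionMatrix) -> MetricsReport:
    """The full metric stack for one confusion matrix."""
    return MetricsReport(
        per_class=per_class_metrics(cm),
        accuracy=overall_accuracy(cm),
        macro_f1=macro_f1(cm),
        kappa=round(cohens_kappa(cm), 2),
        confusion=cm,
    )
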