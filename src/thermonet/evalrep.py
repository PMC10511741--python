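"""Confusion matrices, derived classification statistics, and ROC/AUC.

Conventions: the positive class is RA throughout; per-class precision, recall
and F1 are combined into support-weighted averages; rendered tables round
half-up to two decimals to match the published tables while reports keep full
precision; zero-denominator statistics are reported as 0 with a flag.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "ClassStats",
    "ClassificationReport",
    "RocCurve",
    "confusion_matrix",
    "classification_metrics",
    "roc_auc",
    "emit_report",
    "load_report",
    "render_table_row",
    "round2",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TN/FP/FN/TP counts with RA as the positive class."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self):
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def swapped(self) -> "ConfusionMatrix":
        """The same matrix with the class roles exchanged."""
        return ConfusionMatrix(tn=self.tp, fp=self.fn, fn=self.fp, tp=self.tn)


@dataclass
class ClassStats:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class ClassificationReport:
    normal: ClassStats
    ra: ClassStats
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    accuracy: float
    auc: float | None = None
    zero_division: bool = False


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    """Counts from equal-length binary vectors (truthy = RA)."""
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("label vectors must be equal-length 1-D")
    return ConfusionMatrix(
        tn=int(np.sum(~y_true & ~y_pred)),
        fp=int(np.sum(~y_true & y_pred)),
        fn=int(np.sum(y_true & ~y_pred)),
        tp=int(np.sum(y_true & y_pred)),
    )


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def classification_metrics(cm: ConfusionMatrix) -> ClassificationReport:
    """All derived statistics of a two-class confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    flags = []

    def stats(correct, predicted, support):
        p, f1_ = _safe_div(correct, predicted)
        r, f2_ = _safe_div(correct, support)
        f1, f3_ = _safe_div(2 * p * r, p + r)
        flags.extend([f1_, f2_, f3_])
        return ClassStats(precision=p, recall=r, f1=f1, support=support)

    normal = stats(cm.tn, cm.tn + cm.fn, cm.tn + cm.fp)
    ra = stats(cm.tp, cm.tp + cm.fp, cm.tp + cm.fn)
    n = cm.total
    w_n, w_r = normal.support / n, ra.support / n
    return ClassificationReport(
        normal=normal,
        ra=ra,
        weighted_precision=w_n * normal.precision + w_r * ra.precision,
        weighted_recall=w_n * normal.recall + w_r * ra.recall,
        weighted_f1=w_n * normal.f1 + w_r * ra.f1,
        accuracy=(cm.tp + cm.tn) / n,
        zero_division=any(flags),
    )


def roc_auc(y_true, scores) -> RocCurve:
    """ROC over all score thresholds; AUC by the trapezoidal rule (equal to
    the Mann-Whitney pair statistic with ties counted one half)."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(y_true, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def round2(x: float) -> float:
    """Round half-up to 2 decimals (the published tables' convention)."""
    from decimal import ROUND_HALF_UP, Decimal

    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


def render_table_row(report: ClassificationReport) -> dict:
    """One model's row in the published layout, rounded to 2 decimals."""
    row = {}
    for cls_name, cls in (("Normal", report.normal), ("RA", report.ra)):
        row[cls_name] = {
            "Precision": round2(cls.precision),
            "Recall": round2(cls.recall),
            "F1-measure": round2(cls.f1),
        }
    row["Weighted average"] = {
        "Precision": round2(report.weighted_precision),
        "Recall": round2(report.weighted_recall),
        "F1-measure": round2(report.weighted_f1),
    }
    row["Overall accuracy (%)"] = round2(report.accuracy * 100)
    return row


def _report_dict(report: ClassificationReport) -> dict:
    d = asdict(report)
    if report.auc is None:
        d.pop("auc")
    return d


def emit_report(report: ClassificationReport, path: str, fmt: str = "json") -> None:
    """Write a report as JSON (full precision) or CSV (table layout)."""
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_report_dict(report), fh, indent=2)
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["class", "precision", "recall", "f1", "support"])
            for name, cls in (("normal", report.normal), ("RA", report.ra)):
                writer.writerow([name, repr(cls.precision), repr(cls.recall),
                                 repr(cls.f1), cls.support])
            writer.writerow(["weighted", repr(report.weighted_precision),
                             repr(report.weighted_recall), repr(report.weighted_f1),
                             report.normal.support + report.ra.support])
            writer.writerow(["accuracy", repr(report.accuracy), "", "", ""])
            if report.auc is not None:
                writer.writerow(["auc", repr(report.auc), "", "", ""])
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_report(path: str) -> ClassificationReport:
    """Round-trip loader for JSON reports."""
    with open(path) as fh:
        d = json.load(fh)
    return ClassificationReport(
        normal=ClassStats(**d["normal"]),
        ra=ClassStats(**d["ra"]),
        weighted_precision=d["weighted_precision"],
        weighted_recall=d["weighted_recall"],
        weighted_f1=d["weighted_f1"],
        accuracy=d["accuracy"],
        auc=d.get("auc"),
        zero_division=d["zero_division"],
    )
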