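"""Four-class confusion matrix and per-class Se/Sp/+p/Acc calculus.

Classes follow the AAMI grouping N, S, V, F (rows = true class, columns =
predicted class). Reported percentages are rounded half-up to two decimals.
"""
from __future__ import annotations

import io
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

CLASSES: tuple[str, ...] = ("N", "S", "V", "F")


def round2(x: float) -> float:
    """Round half-up to two decimals (matches printed-table conventions)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClassCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class ClassMetrics:
    se: float
    sp: float
    ppv: float | None
    acc: float


@dataclass(frozen=True)
class ConfusionMatrix:
    """4x4 matrix of true-class (rows) vs predicted-class (columns) counts."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (len(self.classes), len(self.classes)):
            raise ValueError(f"confusion matrix must be {len(self.classes)}x{len(self.classes)}")
        if (counts < 0).any():
            raise ValueError("confusion matrix entries must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.counts, index=list(self.classes),
                          columns=[c.lower() for c in self.classes])
        df.to_csv(path, index_label="true")

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        classes = tuple(str(c) for c in df.index)
        return cls(df.to_numpy(dtype=np.int64), classes)


def confusion_matrix(y_true, y_pred, classes: tuple[str, ...] = CLASSES) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[idx[str(t)], idx[str(p)]] += 1
    return ConfusionMatrix(counts, classes)


def class_counts(cm: ConfusionMatrix, cls: str) -> ClassCounts:
    """One-vs-rest TP/FN/FP/TN partition for ``cls``."""
    i = cm.classes.index(cls)
    c = cm.counts
    tp = int(c[i, i])
    fn = int(c[i, :].sum() - tp)
    fp = int(c[:, i].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)
    return ClassCounts(tp=tp, fn=fn, fp=fp, tn=tn)


def class_metrics(cc: ClassCounts) -> ClassMetrics:
    if cc.tp + cc.fn == 0:
        raise ValueError("class has no true members (tp + fn = 0)")
    se = 100.0 * cc.tp / (cc.tp + cc.fn)
    sp = 100.0 * cc.tn / (cc.tn + cc.fp)
    ppv = None if cc.tp + cc.fp == 0 else 100.0 * cc.tp / (cc.tp + cc.fp)
    acc = 100.0 * (cc.tp + cc.tn) / cc.total
    return ClassMetrics(se=se, sp=sp, ppv=ppv, acc=acc)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Micro accuracy: 100 * trace / grand total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def report(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class Se/Sp/+p/Acc table (2-decimal percents) plus overall row."""
    rows = {}
    for cls in cm.classes:
        m = class_metrics(class_counts(cm, cls))
        rows[cls] = {
            "Se": round2(m.se),
            "Sp": round2(m.sp),
            "+p": round2(m.ppv) if m.ppv is not None else float("nan"),
            "Acc": round2(m.acc),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.loc["overall", "Acc"] = round2(overall_accuracy(cm))
    return df


def report_text(cm: ConfusionMatrix) -> str:
    buf = io.StringIO()
    report(cm).to_csv(buf, float_format="%.2f", index_label="class")
    return buf.getvalue()
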