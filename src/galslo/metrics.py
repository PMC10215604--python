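"""Confusion-matrix construction and macro-averaged diagnostic metrics.

Each class is scored one-vs-rest from the confusion matrix:

    Sen = TP / (TP + FN)        (sensitivity / recall)
    Spe = TN / (TN + FP)        (specificity)
    Ppr = TP / (TP + FP)        (positive predictivity / precision)
    Acc = (TP + TN) / total     (one-vs-rest accuracy)
    F1  = 2 * Sen * Ppr / (Sen + Ppr)

All metrics are kept as exact doubles on a 0-100 percent scale; the macro row
is the unweighted arithmetic mean of the *unrounded* per-class values (macro
F1 is the mean of per-class F1, not the F1 of macro Sen/Ppr). Rounding
happens only at presentation, half-up to two decimals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "per_class_metrics",
    "macro_report",
    "read_confusion_grid",
    "round_half_up",
]

METRIC_NAMES = ("Sen", "Spe", "Ppr", "Acc", "F1")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (display convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; rows are true classes, columns predictions."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if counts.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if (counts < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))


@dataclass
class MetricsReport:
    """Per-class metric rows plus the macro-average row, in percent."""

    labels: tuple[str, ...]
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float] = field(default_factory=dict)

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        rows = {lab: self.per_class[lab] for lab in self.labels}
        rows["Average"] = self.macro
        df = pd.DataFrame(rows).T[list(METRIC_NAMES)]
        if rounded:
            df = df.map(round_half_up)
        return df

    def to_text(self) -> str:
        df = self.to_frame()
        return df.to_string(float_format=lambda v: f"{v:.2f}")

    def to_json(self) -> str:
        df = self.to_frame()
        return json.dumps({row: {m: df.loc[row, m] for m in METRIC_NAMES}
                           for row in df.index}, indent=2)


def confusion(y_true: Sequence, y_pred: Sequence,
              labels: Sequence[str]) -> ConfusionMatrix:
    """Count matrix with counts[i, j] = #{true == labels[i], pred == labels[j]}."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred differ in length")
    index = {lab: i for i, lab in enumerate(labels)}
    missing = {v for v in y_true + y_pred if v not in index}
    if missing:
        raise ValueError(f"observed symbols not covered by labels: {sorted(map(str, missing))}")
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(tuple(labels), counts)


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: 0/0 encountered, defining the metric as 0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def per_class_metrics(cm: ConfusionMatrix, label: str) -> dict[str, float]:
    """One-vs-rest Sen/Spe/Ppr/Acc/F1 for one class, in percent (unrounded)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if label not in cm.labels:
        raise ValueError(f"unknown class {label!r}")
    k = cm.labels.index(label)
    counts = cm.counts
    tp = float(counts[k, k])
    fn = float(counts[k, :].sum() - tp)
    fp = float(counts[:, k].sum() - tp)
    tn = float(cm.total - tp - fn - fp)
    sen = _safe_ratio(tp, tp + fn, f"Sen[{label}]")
    spe = _safe_ratio(tn, tn + fp, f"Spe[{label}]")
    ppr = _safe_ratio(tp, tp + fp, f"Ppr[{label}]")
    acc = (tp + tn) / cm.total
    f1 = _safe_ratio(2 * sen * ppr, sen + ppr, f"F1[{label}]")
    return {"Sen": 100 * sen, "Spe": 100 * spe, "Ppr": 100 * ppr,
            "Acc": 100 * acc, "F1": 100 * f1}


def macro_report(cm: ConfusionMatrix) -> MetricsReport:
    """Full per-class table plus unweighted macro averages."""
    per_class = {lab: per_class_metrics(cm, lab) for lab in cm.labels}
    macro = {m: float(np.mean([per_class[lab][m] for lab in cm.labels]))
             for m in METRIC_NAMES}
    return MetricsReport(cm.labels, per_class, macro)


def read_confusion_grid(path: str | Path) -> ConfusionMatrix:
    """Read a plain-text confusion grid.

    Format: first non-comment line holds whitespace-separated class labels,
    each following line one row of integer counts (true classes in label
    order). Lines starting with ``#`` are comments.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.strip().startswith("#")]
    if not lines:
        raise ValueError(f"empty confusion grid file: {path}")
    labels = tuple(lines[0].split())
    rows = [[int(v) for v in ln.split()] for ln in lines[1:]]
    return ConfusionMatrix(labels, np.array(rows, dtype=np.int64))
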