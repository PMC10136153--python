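"""Confusion matrices and macro-averaged multi-class evaluation.

Per-class precision, recall, F1 and Matthews correlation are computed from
one-vs-rest marginals of the K x K confusion matrix; macro scores are the
unweighted mean over classes present in the truth. Datasets with a single
cell type report accuracy only (macro F1 / MCC need at least two classes).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LabelMap


@dataclass
class ConfusionMatrix:
    """K x K integer counts; rows are true classes, columns predicted."""

    counts: np.ndarray
    label_map: LabelMap

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.label_map)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for the label map")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.label_map.names,
                            columns=self.label_map.names)


@dataclass
class MetricReport:
    accuracy: float
    macro_precision: float | None
    macro_recall: float | None
    macro_f1: float | None
    mean_mcc: float | None
    per_class: pd.DataFrame
    std: float | None = None
    warnings_: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {"accuracy": self.accuracy, "macro_precision": self.macro_precision,
             "macro_recall": self.macro_recall, "macro_f1": self.macro_f1,
             "mean_mcc": self.mean_mcc, "std": self.std,
             "per_class": self.per_class.to_dict(orient="index")}
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def build_confusion(true_labels, predicted_labels,
                    label_map: LabelMap) -> ConfusionMatrix:
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    unseen_true = sorted(set(true_labels) - set(label_map.names))
    if unseen_true:
        raise ValueError(f"true labels outside map: {unseen_true}")
    yt = label_map.encode(true_labels)
    yp = label_map.encode(predicted_labels)
    k = len(label_map)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (yt, yp), 1)
    return ConfusionMatrix(counts, label_map)


def _safe_div(num: float, den: float, what: str, warns: list[str]) -> float:
    if den == 0:
        warns.append(f"{what}: zero denominator, reporting 0")
        return 0.0
    return num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Accuracy plus per-class and macro precision/recall/F1/MCC.

    Undefined ratios (zero denominators, e.g. a never-predicted class) are
    reported as 0 with a warning; this convention affects macro scores for
    degenerate predictors and is deliberate.
    """
    c = cm.counts
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    warns: list[str] = []
    accuracy = float(np.trace(c) / total)
    support = c.sum(axis=1)
    present = np.flatnonzero(support > 0)

    rows = []
    for k in range(len(cm.label_map)):
        tp = float(c[k, k])
        fp = float(c[:, k].sum() - tp)
        fn = float(c[k, :].sum() - tp)
        tn = float(total - tp - fp - fn)
        name = cm.label_map.names[k]
        prec = _safe_div(tp, tp + fp, f"precision[{name}]", warns)
        rec = _safe_div(tp, tp + fn, f"recall[{name}]", warns)
        f1 = _safe_div(2 * prec * rec, prec + rec, f"F1[{name}]", warns)
        mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = _safe_div(tp * tn - fp * fn, mcc_den, f"MCC[{name}]", warns)
        rows.append({"class": name, "precision": prec, "recall": rec,
                     "f1": f1, "mcc": mcc, "support": int(support[k])})
    per_class = pd.DataFrame(rows).set_index("class")

    if len(present) < 2:
        # single observed class: macro metrics are not meaningful
        macro = dict(macro_precision=None, macro_recall=None,
                     macro_f1=None, mean_mcc=None)
    else:
        sub = per_class.iloc[present]
        macro = dict(macro_precision=float(sub["precision"].mean()),
                     macro_recall=float(sub["recall"].mean()),
                     macro_f1=float(sub["f1"].mean()),
                     mean_mcc=float(sub["mcc"].mean()))
    for w in warns:
        warnings.warn(w)
    return MetricReport(accuracy=accuracy, per_class=per_class,
                        warnings_=warns, **macro)


def multiclass_mcc(cm: ConfusionMatrix) -> float:
    """Single K-class Matthews coefficient (alternative to the per-class mean)."""
    c = cm.counts.astype(np.float64)
    t = c.sum(axis=1)  # true occurrences
    p = c.sum(axis=0)  # predicted occurrences
    n = c.sum()
    cov_tp = np.trace(c) * n - t @ p
    den = np.sqrt(n * n - p @ p) * np.sqrt(n * n - t @ t)
    return float(cov_tp / den) if den else 0.0


def replicate_std(values) -> float:
    """Sample standard deviation (n-1 denominator) across replicate runs."""
    values = np.asarray(list(values), dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 replicate values")
    return float(np.std(values, ddof=1))


def per_class_accuracy(cm: ConfusionMatrix) -> pd.Series:
    """Row-normalised diagonal (= per-class recall); zero-support classes omitted."""
    support = cm.counts.sum(axis=1)
    present = np.flatnonzero(support > 0)
    vals = cm.counts[present, present] / support[present]
    return pd.Series(vals, index=[cm.label_map.names[i] for i in present],
                     name="accuracy")
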