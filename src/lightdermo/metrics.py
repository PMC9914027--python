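"""Evaluation statistics from a 7x7 confusion matrix.

Each class is scored one-vs-rest: accuracy, sensitivity (recall),
specificity and precision on the 0-100 percent scale,

    ACC = (TP + TN) / (TP + TN + FP + FN) x 100
    SE  = TP / (TP + FN) x 100
    SP  = TN / (TN + FP) x 100
    PR  = TP / (TP + FP) x 100

and on the fractional scale the F1 score 2*pr*se/(pr+se) and the Matthews
correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

a correlation statistic in [-1, 1] that is robust to class imbalance.  The
macro report averages the per-class values without weighting and adds the
overall accuracy trace/total.  Fractional F1/MCC are canonical; a
percent-scale view is provided for readability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CLASSES

__all__ = [
    "BinaryCounts",
    "MetricsReport",
    "binarize",
    "compute_metrics",
    "confusion_matrix",
    "macro_report",
]

METRIC_NAMES = ("ACC", "SE", "SP", "PR", "F1", "MCC")


@dataclass(frozen=True)
class BinaryCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_matrix(y_true, y_pred, n_classes: int | None = None) -> np.ndarray:
    """Counts matrix, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=np.intp)
    y_pred = np.asarray(y_pred, dtype=np.intp)
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def binarize(cm: np.ndarray, k: int) -> BinaryCounts:
    """One-vs-rest reduction of a multiclass confusion matrix for class k."""
    cm = np.asarray(cm)
    tp = int(cm[k, k])
    fn = int(cm[k].sum() - tp)
    fp = int(cm[:, k].sum() - tp)
    tn = int(cm.sum() - tp - fn - fp)
    return BinaryCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting 0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(b: BinaryCounts) -> dict[str, float]:
    """Per-class metric set; ACC/SE/SP/PR in percent, F1 and MCC fractional.

    Zero-denominator ratios are reported as 0 with a warning so that macro
    averages stay defined when a class is absent from a fold.
    """
    if b.total < 1:
        raise ValueError("need at least one sample")
    acc = _ratio(b.tp + b.tn, b.total, "ACC") * 100.0
    se = _ratio(b.tp, b.tp + b.fn, "SE") * 100.0
    sp = _ratio(b.tn, b.tn + b.fp, "SP") * 100.0
    pr = _ratio(b.tp, b.tp + b.fp, "PR") * 100.0
    f1 = _ratio(2 * (pr / 100.0) * (se / 100.0), pr / 100.0 + se / 100.0, "F1")
    mcc_den = np.sqrt(
        float(b.tp + b.fp) * (b.tp + b.fn) * (b.tn + b.fp) * (b.tn + b.fn)
    )
    mcc = _ratio(float(b.tp) * b.tn - float(b.fp) * b.fn, mcc_den, "MCC")
    return {"ACC": acc, "SE": se, "SP": sp, "PR": pr, "F1": f1, "MCC": mcc}


@dataclass
class MetricsReport:
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    overall_accuracy: float
    n_samples: int

    def macro_percent(self) -> dict[str, float]:
        """Percent-scale view (F1 and MCC multiplied by 100)."""
        out = dict(self.macro)
        out["F1"] = out["F1"] * 100.0
        out["MCC"] = out["MCC"] * 100.0
        return out

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "macro": self.macro,
            "macro_percent": self.macro_percent(),
            "overall_accuracy": self.overall_accuracy,
            "n_samples": self.n_samples,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def per_class_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_class).T[list(METRIC_NAMES)]


def macro_report(cm: np.ndarray, class_names=CLASSES) -> MetricsReport:
    """Per-class one-vs-rest metrics plus their unweighted macro average."""
    cm = np.asarray(cm)
    total = int(cm.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    if cm.shape[0] != len(class_names):
        class_names = [f"class{i}" for i in range(cm.shape[0])]
    per_class = {
        name: compute_metrics(binarize(cm, k)) for k, name in enumerate(class_names)
    }
    macro = {
        m: float(np.mean([per_class[name][m] for name in per_class]))
        for m in METRIC_NAMES
    }
    overall = float(np.trace(cm) / total * 100.0)
    return MetricsReport(
        per_class=per_class, macro=macro, overall_accuracy=overall, n_samples=total
    )
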