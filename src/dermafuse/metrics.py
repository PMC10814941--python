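"""Confusion-matrix bookkeeping and the evaluation metric suite.

For class c of a K×K confusion matrix (rows = true, columns = predicted):

* Sens (sensitivity / recall) = tp / (tp + Σfn)
* Spec (specificity)          = Σtn / (Σtn + Σfp)
* Prec (precision)            = tp / (tp + Σfp)
* F1 = 2·Prec·Sens / (Prec + Sens)
* IoU (intersection over union) = tp / (tp + Σfn + Σfp)

Macro metrics are unweighted means over classes (the mean IoU is written
mIoU); across-class standard deviations accompany the means.  Ratios with a
zero denominator (a class absent from both truth and prediction) are
reported as 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_from_predictions",
    "metrics_from_confusion",
    "threshold_curves",
    "roc_curves",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K×K counts; rows index the true class, columns the predicted class."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        k = len(self.labels)
        if c.shape != (k, k):
            raise ValueError("counts must be K x K for K labels")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self, i: int) -> int:
        return int(self.counts[i, i])

    def fn(self, i: int) -> int:
        return int(self.counts[i].sum() - self.counts[i, i])

    def fp(self, i: int) -> int:
        return int(self.counts[:, i].sum() - self.counts[i, i])

    def tn(self, i: int) -> int:
        return self.total - self.tp(i) - self.fn(i) - self.fp(i)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def confusion_from_predictions(
    y_true: Sequence[str], y_pred: Sequence[str], labels: Sequence[str]
) -> ConfusionMatrix:
    """Count (true, predicted) label pairs into a confusion matrix."""
    labels = tuple(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred, strict=True):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, labels)


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and macro-averaged evaluation metrics."""

    per_class: pd.DataFrame  # index = class, columns = Sens/Spec/Prec/F1/IoU
    undefined: tuple[str, ...] = ()  # classes with zero-denominator ratios

    @property
    def macro(self) -> pd.Series:
        """Unweighted class means (the IoU mean is the mIoU)."""
        return self.per_class.mean(axis=0)

    @property
    def macro_std(self) -> pd.Series:
        """Across-class standard deviation of each metric."""
        return self.per_class.std(axis=0, ddof=1)

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class.to_dict(orient="index"),
            "macro": self.macro.to_dict(),
            "macro_std": self.macro_std.to_dict(),
            "undefined_classes": list(self.undefined),
        }


def _safe_ratio(num: float, den: float, flags: list, cls: str) -> float:
    if den == 0:
        flags.append(cls)
        return 0.0
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Compute Sens/Spec/Prec/F1/IoU per class plus macro means."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []
    rows = {}
    for i, cls in enumerate(cm.labels):
        tp, fn, fp, tn = cm.tp(i), cm.fn(i), cm.fp(i), cm.tn(i)
        sens = _safe_ratio(tp, tp + fn, flags, cls)
        spec = _safe_ratio(tn, tn + fp, flags, cls)
        prec = _safe_ratio(tp, tp + fp, flags, cls)
        f1 = _safe_ratio(2 * prec * sens, prec + sens, flags, cls)
        iou = _safe_ratio(tp, tp + fn + fp, flags, cls)
        rows[cls] = {"Sens": sens, "Spec": spec, "Prec": prec, "F1": f1, "IoU": iou}
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    return MetricsReport(per_class=per_class, undefined=tuple(dict.fromkeys(flags)))


def _one_vs_rest_counts(
    probs: pd.DataFrame, y_true: Sequence[str], cls: str, thresholds: np.ndarray
):
    p = probs[cls].to_numpy()
    positive = np.asarray([t == cls for t in y_true])
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    pred_pos = p[None, :] >= thresholds[:, None]  # (T, n)
    tp = (pred_pos & positive[None, :]).sum(axis=1)
    fp = (pred_pos & ~positive[None, :]).sum(axis=1)
    return tp, fp, n_pos, n_neg


def threshold_curves(
    probs: pd.DataFrame, y_true: Sequence[str], *, step: float = 0.01
) -> pd.DataFrame:
    """FPR and FNR vs decision threshold, one-vs-rest per class.

    An observation is called positive for a class when its predicted
    probability for that class is >= the threshold; the threshold sweeps a
    fixed grid from 0 to 1.  Returns a long-format frame with columns
    ``class, threshold, FPR, FNR``.
    """
    thresholds = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    frames = []
    for cls in probs.columns:
        tp, fp, n_pos, n_neg = _one_vs_rest_counts(probs, y_true, cls, thresholds)
        fnr = 1.0 - tp / n_pos if n_pos else np.zeros_like(thresholds)
        fpr = fp / n_neg if n_neg else np.zeros_like(thresholds, dtype=float)
        frames.append(
            pd.DataFrame(
                {"class": cls, "threshold": thresholds, "FPR": fpr, "FNR": fnr}
            )
        )
    return pd.concat(frames, ignore_index=True)


def roc_curves(
    probs: pd.DataFrame, y_true: Sequence[str], *, step: float = 0.01
) -> pd.DataFrame:
    """One-vs-rest ROC points (FPR, TPR) on the same fixed threshold grid."""
    curves = threshold_curves(probs, y_true, step=step)
    curves = curves.assign(TPR=1.0 - curves["FNR"])
    return curves[["class", "threshold", "FPR", "TPR"]]
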