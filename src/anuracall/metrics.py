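"""Confusion matrices and the eight per-class classification metrics.

Every metric reduces the multi-class confusion matrix one class at a time to
the binary counts (TP, FN, FP, TN) of that class against the rest:

    ACC = (TP+TN)/(TP+TN+FP+FN)     ERR = (FP+FN)/(TP+TN+FP+FN)
    PRC = TP/(TP+FP)                SNS = TP/(TP+FN)
    SPC = TN/(TN+FP)                ROC = sqrt((SNS^2+SPC^2)/2)
    F1  = 2*PRC*SNS/(PRC+SNS)       GM  = sqrt(SNS*SPC)

With imbalanced classes, accuracy and precision are skewed toward the
majority class; the sensitivity/specificity combinations (GM, and the single
ROC-space summary statistic) are the preferred model-selection metrics.
Macro averages are unweighted over classes; per-class metrics with a zero
denominator are undefined and excluded (not zeroed) from the macro mean,
with the number of exclusions reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

logger = logging.getLogger(__name__)

METRIC_NAMES = ("ACC", "ERR", "PRC", "SNS", "SPC", "ROC", "F1", "GM")


@dataclass
class ConfusionMatrix:
    """Count matrix, rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percent(self) -> pd.DataFrame:
        """Row-normalized percentage view (each true class sums to 100 %)."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        sums[sums == 0] = np.nan
        return pd.DataFrame(100.0 * self.counts / sums,
                            index=self.classes, columns=self.classes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes,
                            columns=self.classes)


def confusion(y_true, y_pred, classes=None) -> ConfusionMatrix:
    """Multi-class confusion matrix from two equal-length label sequences."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    if classes is None:
        classes = sorted(np.unique(np.concatenate([y_true, y_pred])).tolist())
    else:
        classes = list(classes)
        seen = set(np.unique(np.concatenate([y_true, y_pred])).tolist())
        if not seen <= set(classes):
            raise ValueError(f"labels {seen - set(classes)} outside class list")
    counts = _sk_confusion(y_true, y_pred, labels=classes)
    return ConfusionMatrix(counts=counts, classes=classes)


def binary_reduce(cm: ConfusionMatrix, positive_class
                  ) -> tuple[int, int, int, int]:
    """One-vs-rest counts (TP, FN, FP, TN) for ``positive_class``."""
    if positive_class not in cm.classes:
        raise ValueError(f"{positive_class!r} is not a class of this matrix")
    i = cm.classes.index(positive_class)
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i].sum() - tp)
    fp = int(cm.counts[:, i].sum() - tp)
    tn = int(cm.total - tp - fn - fp)
    return tp, fn, fp, tn


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else np.nan


def geometric_mean(sns: float, spc: float) -> float:
    """GM = sqrt(SNS * SPC)."""
    return float(np.sqrt(sns * spc))


def roc_statistic(sns: float, spc: float) -> float:
    """Single ROC-space summary: sqrt((SNS^2 + SPC^2) / 2)."""
    return float(np.sqrt((sns**2 + spc**2) / 2.0))


def f1_score(prc: float, sns: float) -> float:
    """F1 = 2 * PRC * SNS / (PRC + SNS)."""
    return float(_safe_div(2.0 * prc * sns, prc + sns))


def binary_metrics(tp: int, fn: int, fp: int, tn: int) -> dict[str, float]:
    """The eight metrics from one set of binary counts (NaN if undefined)."""
    total = tp + fn + fp + tn
    acc = _safe_div(tp + tn, total)
    err = _safe_div(fp + fn, total)
    prc = _safe_div(tp, tp + fp)
    sns = _safe_div(tp, tp + fn)
    spc = _safe_div(tn, tn + fp)
    roc = roc_statistic(sns, spc) if not (np.isnan(sns) or np.isnan(spc)) else np.nan
    f1 = (f1_score(prc, sns)
          if not (np.isnan(prc) or np.isnan(sns)) else np.nan)
    gm = geometric_mean(sns, spc) if not (np.isnan(sns) or np.isnan(spc)) else np.nan
    return {"ACC": acc, "ERR": err, "PRC": prc, "SNS": sns, "SPC": spc,
            "ROC": roc, "F1": f1, "GM": gm}


@dataclass
class MetricsReport:
    """Per-class metrics plus unweighted macro averages (all as fractions)."""

    per_class: pd.DataFrame       # classes x 8 metrics
    macro: dict[str, float]
    n_undefined: dict[str, int]   # per metric, classes excluded from macro

    def to_frame(self) -> pd.DataFrame:
        out = self.per_class.copy()
        out.loc["macro"] = pd.Series(self.macro)
        return out


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Eight metrics for every class of the matrix, and their macro mean."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    rows = {}
    for cls in cm.classes:
        rows[cls] = binary_metrics(*binary_reduce(cm, cls))
    per_class = pd.DataFrame(rows).T[list(METRIC_NAMES)]
    macro, n_undef = {}, {}
    for name in METRIC_NAMES:
        col = per_class[name].to_numpy(dtype=float)
        defined = ~np.isnan(col)
        n_undef[name] = int(np.sum(~defined))
        if n_undef[name]:
            logger.info("macro %s excludes %d undefined class value(s)",
                        name, n_undef[name])
        macro[name] = float(np.mean(col[defined])) if defined.any() else np.nan
    return MetricsReport(per_class=per_class, macro=macro, n_undefined=n_undef)


def metrics_from_labels(y_true, y_pred, classes=None) -> MetricsReport:
    """Metrics computed straight from label sequences."""
    return metrics(confusion(y_true, y_pred, classes))


def best_classifier(reports: dict[str, MetricsReport],
                    criterion: str = "GM") -> str:
    """Name of the report maximizing the macro criterion.

    Ties keep the earlier entry (registry/insertion order).
    """
    if not reports:
        raise ValueError("no reports to compare")
    if criterion not in METRIC_NAMES:
        raise ValueError(f"criterion must be one of {METRIC_NAMES}")
    best_name, best_val = None, -np.inf
    for name, rep in reports.items():
        val = rep.macro[criterion]
        if not np.isnan(val) and val > best_val:
            best_name, best_val = name, val
    if best_name is None:
        raise ValueError("every report has an undefined criterion value")
    return best_name
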