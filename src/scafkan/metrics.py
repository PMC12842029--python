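"""Classification metrics.

AUC is computed as the rank statistic over all positive–negative pairs
(ties count one half) — the probability a random positive scores above a
random negative.  Secondary metrics come from the confusion matrix at a
fixed threshold; undefined precision (no predicted positives) is reported
as 0 with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = ["roc_auc", "MetricSet", "compute_metrics", "roc_points"]


def roc_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Mann–Whitney rank AUC; ties contribute 1/2."""
    y = np.asarray(y, int)
    scores = np.asarray(scores, float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = rankdata(scores)          # average ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class MetricSet:
    auc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray                 # [[tn, fp], [fn, tp]]
    threshold: float = 0.5
    precision_undefined: bool = False

    def as_dict(self) -> dict:
        return {"auc": self.auc, "accuracy": self.accuracy,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1, "threshold": self.threshold,
                "confusion": self.confusion.tolist(),
                "precision_undefined": self.precision_undefined}


def compute_metrics(y: np.ndarray, p: np.ndarray,
                    threshold: float = 0.5) -> MetricSet:
    y = np.asarray(y, int)
    p = np.asarray(p, float)
    pred = (p > threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    undefined = (tp + fp) == 0
    precision = 0.0 if undefined else tp / (tp + fp)
    recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return MetricSet(
        auc=roc_auc(y, p),
        accuracy=(tp + tn) / len(y),
        precision=precision,
        recall=recall,
        f1=f1,
        confusion=np.array([[tn, fp], [fn, tp]]),
        threshold=threshold,
        precision_undefined=undefined,
    )


def roc_points(y: np.ndarray, p: np.ndarray) -> np.ndarray:
    """(fpr, tpr) pairs at every distinct score threshold, for plotting."""
    y = np.asarray(y, int)
    order = np.argsort(-np.asarray(p, float), kind="stable")
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    n_pos, n_neg = y.sum(), len(y) - y.sum()
    tpr = np.concatenate([[0.0], tps / max(n_pos, 1)])
    fpr = np.concatenate([[0.0], fps / max(n_neg, 1)])
    return np.column_stack([fpr, tpr])
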