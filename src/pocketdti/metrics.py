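"""Binary-classification metrics with validation-anchored thresholding.

ROC-AUC and PR-AUC summarise ranking quality; sensitivity and specificity
are reported at the score threshold that maximises F1 on the validation
fold, then held fixed for the evaluation fold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class MetricReport:
    roc_auc: float
    pr_auc: float
    sensitivity: float
    specificity: float
    threshold: float

    def as_dict(self) -> dict[str, float]:
        return {"roc_auc": self.roc_auc, "pr_auc": self.pr_auc,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "threshold": self.threshold}


def _check_two_classes(labels: np.ndarray, what: str) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError(f"{what} fold contains a single class; AUC undefined")


def best_f1_threshold(labels: np.ndarray, scores: np.ndarray) -> float:
    """Scan all distinct scores as thresholds; return the F1-maximising one.

    Predictions are positive when score >= threshold; ties in F1 resolve to
    the lowest qualifying threshold for determinism.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    best_t, best_f1 = 0.5, -1.0
    for t in np.unique(scores):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1:
            best_f1, best_t = f1, float(t)
    return best_t


def evaluate(labels: np.ndarray, scores: np.ndarray,
             valid_labels: np.ndarray | None = None,
             valid_scores: np.ndarray | None = None) -> MetricReport:
    """Metric report for one fold; the threshold comes from the validation
    scores when given, else from the fold itself."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(labels) == 0:
        raise ValueError("empty fold")
    _check_two_classes(labels, "evaluation")
    if valid_labels is not None and valid_scores is not None:
        threshold = best_f1_threshold(np.asarray(valid_labels), np.asarray(valid_scores))
    else:
        threshold = best_f1_threshold(labels, scores)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return MetricReport(
        roc_auc=float(roc_auc_score(labels, scores)),
        pr_auc=float(average_precision_score(labels, scores)),
        sensitivity=sens, specificity=spec, threshold=threshold)
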