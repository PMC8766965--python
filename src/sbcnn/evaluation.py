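"""Classification and detection metrics with multi-trial averaging.

Accuracy, ROC curve + AUC, precision-recall curve + (mean) average
precision.  Curve computation is delegated to scikit-learn; average
precision uses all-points step integration (sum over recall increments of
the precision at that threshold).  Stochastic experiments are averaged
over trials (default 5) with derived seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

__all__ = [
    "TrialReport",
    "roc_curve_auc",
    "pr_curve_map",
    "detection_pr_map",
    "classification_metrics",
    "run_trials",
]


@dataclass
class TrialReport:
    """Per-trial metric values with mean/std aggregation."""

    values: list
    mean: dict
    std: dict
    n_trials: int


def _check_binary(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("both classes must be present in labels")


def roc_curve_auc(scores: np.ndarray, labels: np.ndarray):
    """Threshold-sweep ROC curve and trapezoid AUC (ties grouped).

    Returns ``(fpr, tpr, auc)``.  Raises if labels contain one class only.
    """
    labels = np.asarray(labels)
    _check_binary(labels)
    fpr, tpr, _ = _skm.roc_curve(labels, np.asarray(scores, dtype=np.float64))
    return fpr, tpr, float(_skm.auc(fpr, tpr))


def pr_curve_map(scores: np.ndarray, labels: np.ndarray):
    """Precision-recall curve and average precision (all-points step sum).

    Returns ``(precision, recall, ap)``.  Raises with zero positives.
    """
    labels = np.asarray(labels)
    if np.sum(labels == 1) == 0:
        raise ValueError("at least one positive label is required")
    scores = np.asarray(scores, dtype=np.float64)
    precision, recall, _ = _skm.precision_recall_curve(labels, scores)
    ap = float(_skm.average_precision_score(labels, scores))
    return precision, recall, ap


def detection_pr_map(det_scores: np.ndarray, det_is_tp: np.ndarray, n_truth: int):
    """Average precision for a detector from scored, matched detections.

    ``det_is_tp`` flags each detection (any image) as a true positive per
    the greedy IoU matching; ``n_truth`` is the total ground-truth count.
    Detections are ranked by descending score; AP = sum over detections of
    precision at each recall increment.
    """
    if n_truth < 1:
        raise ValueError("need at least one ground-truth object")
    det_scores = np.asarray(det_scores, dtype=np.float64)
    det_is_tp = np.asarray(det_is_tp, dtype=bool)
    if det_scores.size == 0:
        return np.array([]), np.array([]), 0.0
    order = np.argsort(-det_scores, kind="stable")
    tp = np.cumsum(det_is_tp[order])
    fp = np.cumsum(~det_is_tp[order])
    recall = tp / n_truth
    precision = tp / (tp + fp)
    d_recall = np.diff(np.concatenate([[0.0], recall]))
    ap = float(np.sum(precision * d_recall))
    return precision, recall, ap


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def classification_metrics(scores: np.ndarray, labels: np.ndarray) -> dict:
    """Accuracy, macro mAP and macro ROC AUC from class-score columns.

    ``scores`` is (B, K); integer scores from the binarized pipeline are
    accepted (only their ordering matters).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    acc = float((np.argmax(scores, axis=1) == labels).mean())
    k = scores.shape[1]
    aps, aucs = [], []
    for c in range(k):
        y = (labels == c).astype(int)
        if y.sum() == 0 or y.sum() == y.size:
            continue
        _, _, ap = pr_curve_map(scores[:, c], y)
        _, _, auc = roc_curve_auc(scores[:, c], y)
        aps.append(ap)
        aucs.append(auc)
    return {"accuracy": acc, "map": float(np.mean(aps)), "roc_auc": float(np.mean(aucs))}


def run_trials(experiment_fn, n_trials: int, base_seed: int) -> TrialReport:
    """Run ``experiment_fn(seed)`` for seeds base_seed..base_seed+n-1.

    Each call returns a dict of metrics; the report aggregates mean and
    std (population, 0 for a single trial).  A failing trial propagates
    with its index attached.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    values = []
    for i in range(n_trials):
        try:
            values.append(experiment_fn(base_seed + i))
        except Exception as exc:
            raise RuntimeError(f"trial {i} (seed {base_seed + i}) failed: {exc}") from exc
    keys = values[0].keys()
    mean = {k: float(np.mean([v[k] for v in values])) for k in keys}
    std = {k: float(np.std([v[k] for v in values])) for k in keys}
    return TrialReport(values=values, mean=mean, std=std, n_trials=n_trials)
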