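"""Confusion matrices, per-class metrics, macro aggregation and ROC.

Conventions: confusion matrices are true-rows by predicted-columns; the
"weighted" (row-normalized) form divides each row by its true-class count
so the diagonal reads per-class recall. Per-class metrics are one-vs-rest
with the 0/0 -> 0 convention for precision/recall/F1. Macro scores are
unweighted class means. ROC analysis is one-vs-rest per class plus a
micro-average pooling all (indicator, score) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from cardioedge.io_formats import RHYTHM_LABELS


@dataclass
class MetricsReport:
    classes: tuple[str, ...]
    confusion_counts: np.ndarray
    confusion_normalized: np.ndarray
    per_class: dict[str, dict[str, float]]
    macro_f1: float
    per_class_auroc: dict[str, float] = field(default_factory=dict)
    micro_auroc: float | None = None
    absent_classes: tuple[str, ...] = ()


def normalized_confusion(
    y_true, y_pred, classes=RHYTHM_LABELS
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Counts and row-normalized confusion matrices.

    Rows for classes absent from ``y_true`` are all-zero and flagged in the
    returned tuple of absent class names.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((k, k), dtype=float)
    for t, p in zip(y_true, y_pred):
        counts[idx[t], idx[p]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    normalized = np.divide(
        counts, row_sums, out=np.zeros_like(counts), where=row_sums > 0
    )
    absent = tuple(c for i, c in enumerate(classes) if row_sums[i, 0] == 0)
    return counts, normalized, absent


def class_metrics(confusion_counts: np.ndarray, classes=RHYTHM_LABELS) -> dict:
    """One-vs-rest TP/FP/FN/TN, accuracy, precision, recall, F1 per class."""
    counts = np.asarray(confusion_counts, dtype=float)
    if counts.size == 0 or counts.shape[0] != counts.shape[1]:
        raise ValueError("confusion matrix must be square and non-empty")
    total = counts.sum()
    out: dict[str, dict[str, float]] = {}
    for i, c in enumerate(classes):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        out[c] = {
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "accuracy": (tp + tn) / total if total > 0 else 0.0,
            "precision": precision, "recall": recall, "f1": f1,
        }
    return out


def aggregate_macro(per_class_scores, decimals: int = 3) -> float:
    """Unweighted mean of per-class scores, rounded for reporting."""
    scores = np.asarray(list(per_class_scores), dtype=float)
    if scores.size == 0 or not np.all(np.isfinite(scores)):
        raise ValueError("need one finite score per class")
    return float(np.round(scores.mean(), decimals))


def roc_micro_auc(
    true_onehot: np.ndarray, class_scores: np.ndarray, classes=RHYTHM_LABELS
) -> tuple[dict[str, float], float]:
    """Per-class one-vs-rest AUROC plus the micro-average over all pooled
    (indicator, score) pairs. Degenerate inputs (constant scores, absent
    classes) yield the chance value 0.5."""
    t = np.asarray(true_onehot, dtype=float)
    s = np.asarray(class_scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError("shape mismatch between truth and scores")
    per_class: dict[str, float] = {}
    for i, c in enumerate(classes):
        col_t, col_s = t[:, i], s[:, i]
        if len(np.unique(col_t)) < 2 or len(np.unique(col_s)) < 2:
            per_class[c] = 0.5
        else:
            per_class[c] = float(roc_auc_score(col_t, col_s))
    flat_t, flat_s = t.ravel(), s.ravel()
    if len(np.unique(flat_t)) < 2 or len(np.unique(flat_s)) < 2:
        micro = 0.5
    else:
        micro = float(roc_auc_score(flat_t, flat_s))
    return per_class, micro


def evaluate_predictions(
    y_true, y_pred, scores: np.ndarray | None = None, classes=RHYTHM_LABELS
) -> MetricsReport:
    """Full evaluation of one prediction set."""
    counts, normalized, absent = normalized_confusion(y_true, y_pred, classes)
    per_class = class_metrics(counts, classes)
    macro = aggregate_macro([m["f1"] for m in per_class.values()])
    report = MetricsReport(
        classes=tuple(classes),
        confusion_counts=counts,
        confusion_normalized=normalized,
        per_class=per_class,
        macro_f1=macro,
        absent_classes=absent,
    )
    if scores is not None:
        onehot = np.stack(
            [(np.asarray(y_true) == c).astype(float) for c in classes], axis=1
        )
        report.per_class_auroc, report.micro_auroc = roc_micro_auc(
            onehot, scores, classes
        )
    return report
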