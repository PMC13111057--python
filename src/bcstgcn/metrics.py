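"""Classification and keypoint-localization metrics.

Accuracy is the pooled fraction of correct predictions (trace of the
confusion matrix over its total).  Precision and recall are computed
one-vs-rest per class as TP/(TP+FP) and TP/(TP+FN) and macro-averaged by
default (micro averaging is available behind a flag); F1 is the harmonic
mean of the macro precision and recall.  Keypoint localization error is the
root mean square error in pixels, per keypoint and pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MetricsReport:
    confusion: np.ndarray
    confusion_norm: np.ndarray
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    labels: tuple


@dataclass(frozen=True)
class KeypointErrorReport:
    per_keypoint_rmse: np.ndarray
    overall_rmse: float
    keypoint_names: tuple = ()


def confusion_matrix(y_true, y_pred, n_classes: int | None = None,
                     labels=None):
    """Counts[i, j] = #(true class i predicted as class j), plus the
    row-normalized form (zero rows stay zero).

    Non-integer label vectors are encoded through ``labels`` (or their
    sorted unique values when ``labels`` is omitted).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if not np.issubdtype(y_true.dtype, np.integer):
        order = list(labels) if labels is not None else sorted(
            set(y_true.tolist()) | set(y_pred.tolist()))
        lut = {lab: i for i, lab in enumerate(order)}
        y_true = np.array([lut[v] for v in y_true.tolist()])
        y_pred = np.array([lut[v] for v in y_pred.tolist()])
        n_classes = n_classes or len(order)
    elif labels is not None:
        n_classes = n_classes or len(labels)
    y_true = y_true.astype(int)
    y_pred = y_pred.astype(int)
    k = n_classes or int(max(y_true.max(), y_pred.max())) + 1
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    row = counts.sum(axis=1, keepdims=True)
    norm = np.divide(counts, row, out=np.zeros((k, k)), where=row > 0)
    return counts, norm


def accuracy(confusion: np.ndarray) -> float:
    """Pooled accuracy: trace over total."""
    confusion = np.asarray(confusion)
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(confusion) / total)


def _per_class(confusion: np.ndarray):
    tp = np.diag(confusion).astype(float)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    return tp, fp, fn


def _macro(values: np.ndarray, valid: np.ndarray, what: str) -> float:
    if not valid.all():
        warnings.warn(
            f"classes {np.flatnonzero(~valid).tolist()} have zero "
            f"denominator for {what}; excluded from the macro mean",
            RuntimeWarning, stacklevel=3)
    if not valid.any():
        raise ValueError(f"no class has a valid {what} denominator")
    return float(values[valid].mean())


def precision(confusion: np.ndarray, average: str = "macro") -> float:
    """TP/(TP+FP), macro-averaged over classes (or micro behind the flag)."""
    tp, fp, _ = _per_class(np.asarray(confusion))
    if average == "micro":
        return float(tp.sum() / (tp.sum() + fp.sum()))
    valid = (tp + fp) > 0
    vals = np.divide(tp, tp + fp, out=np.zeros_like(tp), where=valid)
    return _macro(vals, valid, "precision")


def recall(confusion: np.ndarray, average: str = "macro") -> float:
    """TP/(TP+FN), macro-averaged over classes (or micro behind the flag)."""
    tp, _, fn = _per_class(np.asarray(confusion))
    if average == "micro":
        return float(tp.sum() / (tp.sum() + fn.sum()))
    valid = (tp + fn) > 0
    vals = np.divide(tp, tp + fn, out=np.zeros_like(tp), where=valid)
    return _macro(vals, valid, "recall")


def f1_score(confusion: np.ndarray, average: str = "macro") -> float:
    """Harmonic mean of the (macro) precision and recall."""
    p = precision(confusion, average)
    r = recall(confusion, average)
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def rmse(y_true, y_pred) -> float:
    """Root mean square error sqrt(mean((y - y_hat)^2))."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("inputs must have equal length")
    if y_true.size == 0:
        raise ValueError("rmse of empty input")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def keypoint_rmse(true_coords: np.ndarray, pred_coords: np.ndarray,
                  keypoint_names=()) -> KeypointErrorReport:
    """Per-keypoint and pooled RMSE of (T, V, 2) coordinate arrays."""
    true_coords = np.asarray(true_coords, dtype=float)
    pred_coords = np.asarray(pred_coords, dtype=float)
    if true_coords.shape != pred_coords.shape:
        raise ValueError("coordinate arrays must have equal shape")
    sq = (true_coords - pred_coords) ** 2
    per_kp = np.sqrt(sq.mean(axis=(0, 2)))
    overall = float(np.sqrt(sq.mean()))
    return KeypointErrorReport(per_keypoint_rmse=per_kp, overall_rmse=overall,
                               keypoint_names=tuple(keypoint_names))


def evaluate(y_true, y_pred, labels=None, average: str = "macro") -> MetricsReport:
    """Full report: confusion matrix plus the four classification metrics."""
    counts, norm = confusion_matrix(y_true, y_pred, labels=labels)
    tp, fp, fn = _per_class(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        pc_p = np.where((tp + fp) > 0, tp / np.maximum(tp + fp, 1), 0.0)
        pc_r = np.where((tp + fn) > 0, tp / np.maximum(tp + fn, 1), 0.0)
    return MetricsReport(
        confusion=counts,
        confusion_norm=norm,
        accuracy=accuracy(counts),
        precision=precision(counts, average),
        recall=recall(counts, average),
        f1=f1_score(counts, average),
        per_class_precision=pc_p,
        per_class_recall=pc_r,
        labels=tuple(labels) if labels is not None else tuple(range(counts.shape[0])),
    )


def report_to_tsv(report: MetricsReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for name in ("accuracy", "precision", "recall", "f1"):
            fh.write(f"{name}\t{getattr(report, name):.6f}\n")
        fh.write("\nconfusion\t" + "\t".join(map(str, report.labels)) + "\n")
        for lab, row in zip(report.labels, report.confusion):
            fh.write(str(lab) + "\t" + "\t".join(map(str, row)) + "\n")
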