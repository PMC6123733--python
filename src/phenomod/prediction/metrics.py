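"""Prediction-performance metrics.

Regression quality is summarized by the Pearson correlation r between
predicted and observed values, the coefficient of determination

    R² = 1 - SS_res / SS_tot = 1 - Σ(y_i - ŷ_i)² / Σ(y_i - ȳ)²,

the root mean squared relative error

    RMSRE = sqrt( Σ((y_i - ŷ_i)/y_i)² / s ),

and the predictive bias

    μ = (1/n) Σ (ŷ_i - y_i)/y_i,

where μ > 0 indicates overestimation and μ < 0 underestimation.  RMSRE
and μ are relative-error metrics and are undefined when any observed
value is exactly zero.

Classification quality is summarized by the confusion matrix, accuracy,
ROC curve / AUC (trapezoidal, equal to the Mann–Whitney concordance
probability with ties counted 1/2) and the precision–recall curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_curve

from ..exceptions import MetricError

__all__ = [
    "RegressionMetrics",
    "ClassificationMetrics",
    "regression_metrics",
    "classification_metrics",
    "roc_auc",
    "pr_curve",
    "multiclass_auc",
]


@dataclass(frozen=True)
class RegressionMetrics:
    pcc: float
    pcc_pvalue: float
    r_squared: float
    rmsre: float
    bias: float

    def as_dict(self):
        return {"pcc": self.pcc, "pcc_pvalue": self.pcc_pvalue,
                "r_squared": self.r_squared, "rmsre": self.rmsre, "bias": self.bias}


@dataclass(frozen=True)
class ClassificationMetrics:
    classes: tuple
    confusion: np.ndarray
    accuracy: float
    auc: float | None = None
    roc_points: np.ndarray | None = None
    pr_points: np.ndarray | None = None

    def as_dict(self):
        return {"accuracy": self.accuracy, "auc": self.auc}


def _check_pair(observed, predicted):
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise MetricError("observed and predicted must be 1-D of equal length")
    if y.size < 2:
        raise MetricError("need at least 2 observations")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise MetricError("non-finite values in metric input")
    return y, yhat


def regression_metrics(observed, predicted) -> RegressionMetrics:
    """Compute PCC (with two-sided t-test p-value), R², RMSRE and bias μ."""
    y, yhat = _check_pair(observed, predicted)
    if np.any(y == 0):
        raise MetricError(
            "RMSRE and bias are relative-error metrics undefined at y = 0; "
            "use strictly positive observed targets"
        )
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise MetricError("constant observed vector: PCC and R2 undefined")
    r_squared = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    rel = (y - yhat) / y
    rmsre = float(np.sqrt(np.mean(rel**2)))
    bias = float(np.mean((yhat - y) / y))
    if np.ptp(yhat) == 0:
        pcc, pval = 0.0, 1.0  # degenerate constant prediction
    else:
        pcc, pval = stats.pearsonr(y, yhat)
    return RegressionMetrics(float(pcc), float(pval), float(r_squared), rmsre, bias)


def classification_metrics(observed_labels, predicted_labels) -> ClassificationMetrics:
    """Confusion matrix (actual rows × predicted columns) and accuracy.

    Classes are the sorted union of observed and predicted labels.
    """
    obs = np.asarray(observed_labels)
    pred = np.asarray(predicted_labels)
    if obs.size == 0:
        raise MetricError("empty label vectors")
    if obs.shape != pred.shape:
        raise MetricError("label vectors must have equal length")
    classes = np.unique(np.concatenate([obs, pred]))
    index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    for a, p in zip(obs, pred):
        confusion[index[a], index[p]] += 1
    accuracy = float(np.trace(confusion) / obs.size)
    return ClassificationMetrics(tuple(classes), confusion, accuracy)


def _check_binary(observed_binary, scores):
    obs = np.asarray(observed_binary)
    s = np.asarray(scores, dtype=float)
    if obs.shape != s.shape or obs.ndim != 1:
        raise MetricError("labels and scores must be 1-D of equal length")
    classes = np.unique(obs)
    if classes.size != 2:
        raise MetricError(f"need exactly two classes present, got {classes.tolist()}")
    positive = classes[1]  # larger label is the positive class
    return (obs == positive).astype(int), s


def roc_auc(observed_binary, scores):
    """ROC curve by threshold sweep and its trapezoidal AUC.

    Returns ``(roc_points, auc)`` where ``roc_points`` is an (m, 2) array
    of (FPR, TPR) pairs running from (0, 0) to (1, 1).
    """
    y, s = _check_binary(observed_binary, scores)
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def pr_curve(observed_binary, scores):
    """Precision–recall pairs along the threshold sweep (strict → loose)."""
    y, s = _check_binary(observed_binary, scores)
    if y.sum() == 0:
        raise MetricError("no positive labels: precision-recall undefined")
    precision, recall, _ = precision_recall_curve(y, s)
    # sklearn returns loosest-first plus a trailing (precision=1, recall=0)
    # sentinel; emit strictest-to-loosest with recall non-decreasing.
    return np.column_stack([recall[-2::-1], precision[-2::-1]])


def multiclass_auc(observed_labels, score_matrix, classes):
    """Macro-averaged one-vs-rest AUC.

    ``score_matrix`` is (n, c) with columns ordered like ``classes``.
    Classes absent from ``observed_labels`` are skipped.
    """
    obs = np.asarray(observed_labels)
    aucs = []
    for j, cls in enumerate(classes):
        y = (obs == cls).astype(int)
        if y.min() == y.max():
            continue
        _, auc = roc_auc(y, np.asarray(score_matrix)[:, j])
        aucs.append(auc)
    if not aucs:
        raise MetricError("no class with both positives and negatives present")
    return float(np.mean(aucs))
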