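"""Losses and the three-level evaluation stack.

The headline loss is TMSE — the mean over all scalar elements of
``tan((y - y_hat)^2)``.  Squared residuals are clamped to [0, 1] before the
tangent, keeping the map inside the first branch of tan; for one-hot targets
and probability predictions residuals never exceed 1, so the clamp is
inactive in classification use and only guards regression misuse.  For small
residuals ``tan(s) ~ s``, so TMSE approaches MSE, and since ``tan(s) >= s``
on [0, pi/2) TMSE dominates MSE on every batch.

Evaluation follows the usual multi-class confusion-matrix stack: per-class
precision, recall and F1 (one-vs-rest counts), overall accuracy as the
fraction of correct predictions, and two "overall F1" aggregates — the mean
over the N/A/O classes (the CinC 2017 scoring convention) and the mean over
all four classes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from .io import CLASS_LABELS

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionBatch",
    "ConfusionMatrix",
    "EvaluationReport",
    "tmse_loss",
    "tmse_grad",
    "mse_loss",
    "cross_entropy_loss",
    "confusion_matrix",
    "evaluate",
]

_EPS = 1e-12


@dataclass
class PredictionBatch:
    """Aligned true one-hot rows and predicted probability rows.

    ``n_elements`` is the flat element count (rows x classes) entering the
    loss denominators.
    """

    y_true: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        self.y_true = np.atleast_2d(np.asarray(self.y_true, dtype=float))
        self.y_pred = np.atleast_2d(np.asarray(self.y_pred, dtype=float))
        if self.y_true.shape != self.y_pred.shape:
            raise ValueError("y_true and y_pred shapes must match")
        if np.any((self.y_pred < -_EPS) | (self.y_pred > 1 + _EPS)):
            raise ValueError("predicted probabilities must lie in [0, 1]")
        if not np.allclose(self.y_true.sum(axis=1), 1.0):
            raise ValueError("true rows must be one-hot (sum to 1)")

    @property
    def n_elements(self) -> int:
        return self.y_true.size


def tmse_loss(batch: PredictionBatch, clamp: float = 1.0) -> float:
    """Tan-mapped squared error: mean over elements of tan(min(r^2, clamp)).

    Zero iff every residual is zero; requires ``clamp < pi/2``.
    """
    if not clamp < math.pi / 2:
        raise ValueError("clamp must be < pi/2 (tan domain)")
    sq = np.minimum((batch.y_true - batch.y_pred) ** 2, clamp)
    return float(np.mean(np.tan(sq)))


def tmse_grad(batch: PredictionBatch, clamp: float = 1.0) -> np.ndarray:
    """Analytic d(TMSE)/d(y_pred): -2(y - y_hat) sec^2((y - y_hat)^2) / N,
    zero where the clamp is active."""
    if not clamp < math.pi / 2:
        raise ValueError("clamp must be < pi/2 (tan domain)")
    r = batch.y_true - batch.y_pred
    sq = r**2
    active = sq < clamp
    sec2 = 1.0 / np.cos(np.minimum(sq, clamp)) ** 2
    return np.where(active, -2.0 * r * sec2, 0.0) / batch.n_elements


def mse_loss(batch: PredictionBatch) -> float:
    """Mean over elements of squared residual."""
    return float(np.mean((batch.y_true - batch.y_pred) ** 2))


def cross_entropy_loss(batch: PredictionBatch, eps: float = 1e-12) -> float:
    """Mean per-row categorical cross-entropy, probabilities clipped at eps."""
    p = np.clip(batch.y_pred, eps, 1.0)
    return float(-np.sum(batch.y_true * np.log(p)) / batch.y_true.shape[0])


@dataclass
class ConfusionMatrix:
    """4x4 counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def class_counts(self, label: str) -> dict[str, int]:
        """One-vs-rest TP/FN/FP/TN for a class."""
        i = self.labels.index(label)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i, :].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return {"TP": tp, "FN": fn, "FP": fp, "TN": tn}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def confusion_matrix(
    y_true: Sequence[str], y_pred: Sequence[str], labels: Sequence[str] = CLASS_LABELS
) -> ConfusionMatrix:
    """Count (true, predicted) label pairs into a ConfusionMatrix."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences must have equal length")
    known = set(labels)
    for lab in (*y_true, *y_pred):
        if lab not in known:
            raise ValueError(f"unknown label {lab!r}")
    if not y_true:
        return ConfusionMatrix(np.zeros((len(labels), len(labels)), dtype=int), tuple(labels))
    counts = _sk_confusion_matrix(y_true, y_pred, labels=list(labels))
    return ConfusionMatrix(counts, tuple(labels))


@dataclass
class EvaluationReport:
    """Per-class precision/recall/F1, accuracy and the overall-F1 aggregates."""

    matrix: ConfusionMatrix
    precision: dict[str, float] = field(default_factory=dict)
    recall: dict[str, float] = field(default_factory=dict)
    f1: dict[str, float] = field(default_factory=dict)
    accuracy: float = 0.0
    overall_f1_nao: float = 0.0  # mean F1 over N, A, O (challenge convention)
    overall_f1_all: float = 0.0  # mean F1 over all four classes

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "overall_f1_nao": self.overall_f1_nao,
            "overall_f1_all": self.overall_f1_all,
            "confusion_matrix": self.matrix.counts.tolist(),
            "labels": list(self.matrix.labels),
        }

    def table_row(self, method: str) -> dict:
        """One row of the ablation-comparison table (F1 per class + overall
        + accuracy)."""
        return {
            "Method": method,
            "F1 Normal": self.f1.get("N", float("nan")),
            "F1 AF": self.f1.get("A", float("nan")),
            "F1 Other": self.f1.get("O", float("nan")),
            "F1 Overall": self.overall_f1_nao,
            "Accuracy": self.accuracy,
        }


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.info("evaluate: %s has zero denominator; reporting 0", what)
        return 0.0
    return num / den


def evaluate(matrix: ConfusionMatrix) -> EvaluationReport:
    """Derive the full evaluation report from a confusion matrix.

    Accuracy is the overall fraction of correct predictions; per-class
    precision/recall/F1 use one-vs-rest counts.  Zero-denominator metrics
    are reported as 0 with a logged note.
    """
    if matrix.total == 0:
        raise ValueError("cannot evaluate an empty confusion matrix")
    precision, recall, f1 = {}, {}, {}
    for lab in matrix.labels:
        c = matrix.class_counts(lab)
        p = _safe_div(c["TP"], c["TP"] + c["FP"], f"precision({lab})")
        r = _safe_div(c["TP"], c["TP"] + c["FN"], f"recall({lab})")
        precision[lab], recall[lab] = p, r
        f1[lab] = _safe_div(2 * p * r, p + r, f"F1({lab})")
    accuracy = float(np.trace(matrix.counts)) / matrix.total
    nao = [f1[lab] for lab in ("N", "A", "O") if lab in f1]
    return EvaluationReport(
        matrix=matrix,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        overall_f1_nao=float(np.mean(nao)) if nao else 0.0,
        overall_f1_all=float(np.mean(list(f1.values()))),
    )
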