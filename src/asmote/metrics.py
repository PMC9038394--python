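"""The eight evaluation quantities: accuracy, precision, recall, F1, MAE,
RMSE, RAE and RRSE, derived from a confusion-count quadruple.

RAE and RRSE normalize the absolute / squared prediction error by the error
of a predict-the-truth-mean baseline; they are stored as fractions here and
multiplied by 100 where table layouts print them as percentages.  Error
metrics operate on 0/1 class labels by default (so accuracy = 1 - MAE); an
option computes them on class probabilities instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConstantTruthError, ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP,
            self.TN + other.TN, self.FN + other.FN,
        )


@dataclass
class MetricsReport:
    """All eight metric values plus the confusion counts they derive from.

    ``rae``/``rrse`` are fractions (1.0 = the mean-predictor baseline);
    ``flags`` records degenerate denominators that were mapped to 0.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    mae: float
    rmse: float
    rae: float
    rrse: float
    counts: ConfusionCounts
    flags: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        return {
            "accuracy": self.accuracy * scale,
            "precision": self.precision * scale,
            "recall": self.recall * scale,
            "f1": self.f1,
            "mae": self.mae,
            "rmse": self.rmse,
            "rae": self.rae * scale,
            "rrse": self.rrse * scale,
            "counts": {"TP": self.counts.TP, "FP": self.counts.FP,
                       "TN": self.counts.TN, "FN": self.counts.FN},
            "flags": list(self.flags),
        }


def _check_binary(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v)
    if not np.isin(v, (0, 1)).all():
        raise ValidationError(f"{name} must contain only 0/1 labels")
    return v.astype(int)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/FP/TN/FN with label 1 as the positive ('disease present') class."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def classification_metrics(c: ConfusionCounts) -> tuple[float, float, float, float, tuple[str, ...]]:
    """Accuracy, precision, recall and F1 from confusion counts.

    Degenerate denominators (no predicted positives, no actual positives,
    precision + recall = 0) yield 0 and are flagged rather than raising.
    """
    if c.total == 0:
        raise ValidationError("cannot compute metrics from zero counts")
    flags: list[str] = []
    accuracy = (c.TP + c.TN) / c.total
    if c.TP + c.FP == 0:
        precision = 0.0
        flags.append("no_predicted_positives")
    else:
        precision = c.TP / (c.TP + c.FP)
    if c.TP + c.FN == 0:
        recall = 0.0
        flags.append("no_actual_positives")
    else:
        recall = c.TP / (c.TP + c.FN)
    if precision + recall == 0:
        f1 = 0.0
        flags.append("zero_precision_and_recall")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return accuracy, precision, recall, f1, tuple(flags)


def error_metrics(y_true, y_pred) -> tuple[float, float, float, float]:
    """MAE, RMSE, RAE and RRSE of numeric predictions against the truth.

    RAE = sum |r_i - r^T_i| / sum |r_i - rbar|;
    RRSE = sqrt(sum (r_i - r^T_i)^2 / sum (r_i - rbar)^2),
    where rbar is the truth mean.  A constant truth makes both denominators
    zero and raises :class:`ConstantTruthError`.
    """
    r = np.asarray(y_true, dtype=float)
    rhat = np.asarray(y_pred, dtype=float)
    if r.shape != rhat.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    if r.size == 0:
        raise ValidationError("empty inputs")
    diff = rhat - r
    p = r.size
    mae = float(np.abs(diff).sum() / p)
    rmse = float(np.sqrt((diff ** 2).sum() / p))
    base = r - r.mean()
    abs_den = float(np.abs(base).sum())
    sq_den = float((base ** 2).sum())
    if abs_den == 0 or sq_den == 0:
        raise ConstantTruthError("relative errors undefined for constant ground truth")
    rae = float(np.abs(diff).sum() / abs_den)
    rrse = float(np.sqrt((diff ** 2).sum() / sq_den))
    return mae, rmse, rae, rrse


def compute_report(y_true, y_pred, proba=None, errors_on="labels") -> MetricsReport:
    """Full :class:`MetricsReport` for one set of predictions.

    ``errors_on="proba"`` computes MAE/RMSE/RAE/RRSE on the positive-class
    probability instead of the hard labels (requires ``proba``).
    """
    c = confusion(y_true, y_pred)
    accuracy, precision, recall, f1, flags = classification_metrics(c)
    if errors_on == "proba":
        if proba is None:
            raise ValidationError("errors_on='proba' requires class probabilities")
        pred_num = np.asarray(proba, dtype=float)
        if pred_num.ndim == 2:
            pred_num = pred_num[:, 1]
    elif errors_on == "labels":
        pred_num = np.asarray(y_pred, dtype=float)
    else:
        raise ValidationError(f"unknown errors_on={errors_on!r}")
    mae, rmse, rae, rrse = error_metrics(y_true, pred_num)
    return MetricsReport(accuracy, precision, recall, f1, mae, rmse, rae, rrse, c, flags)
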