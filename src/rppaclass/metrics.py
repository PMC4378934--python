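"""Confusion matrices and the Matthews correlation coefficient family.

The multiclass MCC (Gorodkin's R_K) is the Pearson correlation between the
n x N one-hot indicator matrices of truth (Y) and prediction (X),

    MCC = cov(X, Y) / sqrt(cov(X, X) * cov(Y, Y)),

with cov(X, Y) the mean over classes of the per-column covariances.  It is
computed here both directly from the indicator matrices and in closed form
from the N x N confusion matrix C (rows = true class, columns = predicted
class); the two routes agree to floating-point precision.  Whenever a
denominator factor vanishes (a degenerate truth or prediction margin) the
coefficient is defined as 0, the no-information value.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ConfusionMatrix",
    "IndicatorPair",
    "confusion",
    "binary_mcc",
    "per_class_mcc",
    "multiclass_mcc",
    "multiclass_mcc_cov",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """N x N count matrix; entry (i, j) = samples of true class i predicted j."""

    classes: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.classes)
        if counts.shape != (n, n):
            raise ValidationError(f"counts shape {counts.shape} != ({n}, {n})")
        if (counts < 0).any():
            raise ValidationError("confusion counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, class_index: int) -> tuple[int, int, int, int]:
        """Collapse to (tp, fp, tn, fn) for one class against the rest."""
        if not (0 <= class_index < len(self.classes)):
            raise ValidationError(f"class index {class_index} out of range")
        c = self.counts
        tp = int(c[class_index, class_index])
        fp = int(c[:, class_index].sum() - tp)
        fn = int(c[class_index, :].sum() - tp)
        tn = int(c.sum() - tp - fp - fn)
        return tp, fp, tn, fn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))


@dataclass(frozen=True)
class IndicatorPair:
    """One-hot truth (Y) and prediction (X) matrices, n samples x N classes."""

    truth: np.ndarray = field(repr=False)
    predicted: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        y = np.asarray(self.truth, dtype=np.float64)
        x = np.asarray(self.predicted, dtype=np.float64)
        if y.shape != x.shape or y.ndim != 2:
            raise ValidationError(f"conformance: truth {y.shape} vs predicted {x.shape}")
        for name, m in (("truth", y), ("predicted", x)):
            if not np.all(np.isin(m, (0.0, 1.0))):
                raise ValidationError(f"{name} matrix must be binary")
            if not np.all(m.sum(axis=1) == 1):
                raise ValidationError(f"every {name} row must sum to exactly 1")
        object.__setattr__(self, "truth", y)
        object.__setattr__(self, "predicted", x)

    @classmethod
    def from_labels(
        cls, true_labels: Sequence[str], predicted_labels: Sequence[str], classes: Sequence[str]
    ) -> "IndicatorPair":
        cm_pos = {c: k for k, c in enumerate(classes)}
        n, nc = len(true_labels), len(classes)
        y = np.zeros((n, nc))
        x = np.zeros((n, nc))
        for i, (t, p) in enumerate(zip(true_labels, predicted_labels)):
            y[i, cm_pos[t]] = 1.0
            x[i, cm_pos[p]] = 1.0
        return cls(truth=y, predicted=x)

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix) -> "IndicatorPair":
        """Expand counts back into per-sample one-hot rows (any sample order)."""
        rows_y, rows_x = [], []
        nc = len(cm.classes)
        eye = np.eye(nc)
        for i in range(nc):
            for j in range(nc):
                k = int(cm.counts[i, j])
                if k:
                    rows_y.append(np.tile(eye[i], (k, 1)))
                    rows_x.append(np.tile(eye[j], (k, 1)))
        if not rows_y:
            raise ValidationError("cannot build indicators from an empty confusion matrix")
        return cls(truth=np.vstack(rows_y), predicted=np.vstack(rows_x))


def confusion(
    true_labels: Sequence[str], predicted_labels: Sequence[str], classes: Sequence[str]
) -> ConfusionMatrix:
    """Tally a confusion matrix in the given class order."""
    if len(true_labels) != len(predicted_labels):
        raise ValidationError("label vectors differ in length")
    pos = {c: k for k, c in enumerate(classes)}
    counts = np.zeros((len(pos), len(pos)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in pos or p not in pos:
            raise ValidationError(f"label outside class list: {t!r} / {p!r}")
        counts[pos[t], pos[p]] += 1
    return ConfusionMatrix(classes=tuple(classes), counts=counts)


def binary_mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Two-class MCC from the four counts; 0 when any denominator factor is 0."""
    if min(tp, fp, tn, fn) < 0:
        raise ValidationError("counts must be nonnegative")
    den = (tn + fn) * (tn + fp) * (tp + fn) * (tp + fp)
    if den == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(den)


def per_class_mcc(cm: ConfusionMatrix, class_index: int) -> float:
    """One-vs-rest MCC for a single class."""
    return binary_mcc(*cm.one_vs_rest(class_index))


def multiclass_mcc(cm: ConfusionMatrix) -> float:
    """Gorodkin multiclass MCC from the confusion matrix.

    Closed form: with s the sample total, c the correctly classified count,
    t_k the true-class totals (row sums) and p_k the predicted totals
    (column sums),

        MCC = (c*s - t.p) / sqrt((s^2 - p.p) * (s^2 - t.t)).
    """
    if cm.total < 1:
        raise ValidationError("confusion matrix holds no samples")
    c = np.asarray(cm.counts, dtype=np.float64)
    s = c.sum()
    corr = np.trace(c)
    t = c.sum(axis=1)
    p = c.sum(axis=0)
    num = corr * s - t @ p
    den_p = s * s - p @ p
    den_t = s * s - t @ t
    if den_p <= 0 or den_t <= 0:
        return 0.0
    return float(num / math.sqrt(den_p * den_t))


def multiclass_mcc_cov(pair: IndicatorPair) -> float:
    """Multiclass MCC as the indicator-matrix correlation cov(X,Y)/sqrt(cov(X,X)cov(Y,Y))."""
    x = pair.predicted
    y = pair.truth

    def cov(a: np.ndarray, b: np.ndarray) -> float:
        # mean over class columns of the per-column sample covariances
        ac = a - a.mean(axis=0, keepdims=True)
        bc = b - b.mean(axis=0, keepdims=True)
        return float((ac * bc).sum() / a.shape[1])

    vx = cov(x, x)
    vy = cov(y, y)
    if vx <= 0 or vy <= 0:
        return 0.0
    return cov(x, y) / math.sqrt(vx * vy)
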