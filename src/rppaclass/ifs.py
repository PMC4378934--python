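"""Incremental feature selection over an mRMR ranking, with k-fold CV.

Features are added one by one from the top of the ranked list; for every
prefix S_i = {f_1, ..., f_i} each requested classifier is evaluated by
stratified k-fold cross-validation on the training set.  Fold predictions
are pooled into a single confusion matrix per (prefix, classifier) and the
multiclass MCC computed once on it; the same fold assignment is reused for
every prefix and every classifier so that curve points are directly
comparable.  The optimal prefix is either the first one whose MCC clears a
threshold (parsimony rule) or the smallest argmax of the curve.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec, TrainedModel, predict, train
from .dataset import ExpressionDataset
from .errors import ValidationError
from .metrics import ConfusionMatrix, confusion, multiclass_mcc, per_class_mcc
from .mrmr import RankedFeatureList

__all__ = [
    "IFSRecord",
    "IFSCurve",
    "stratified_folds",
    "kfold_cv",
    "run_ifs",
    "select_optimal",
    "evaluate_final",
    "plot_curve",
]


@dataclass(frozen=True)
class IFSRecord:
    """CV performance of every classifier at one feature count."""

    feature_count: int
    overall: dict[str, float]  # classifier name -> multiclass MCC
    per_class: dict[str, dict[str, float]]  # classifier -> class -> MCC


@dataclass(frozen=True)
class IFSCurve:
    """The whole IFS table: one record per prefix length."""

    records: tuple[IFSRecord, ...]
    ranked: RankedFeatureList
    cv_folds: int
    seed: int

    def __post_init__(self) -> None:
        counts = [r.feature_count for r in self.records]
        if counts != sorted(set(counts)) or (counts and counts[0] < 1):
            raise ValidationError("records must be strictly increasing feature counts >= 1")

    def classifiers(self) -> tuple[str, ...]:
        return tuple(self.records[0].overall) if self.records else ()

    def mcc_series(self, classifier: str) -> list[tuple[int, float]]:
        if classifier not in self.classifiers():
            raise ValidationError(f"no curve recorded for classifier {classifier!r}")
        return [(r.feature_count, r.overall[classifier]) for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            for clf, mcc in rec.overall.items():
                row: dict[str, object] = {
                    "feature_count": rec.feature_count,
                    "classifier": clf,
                    "mcc": mcc,
                }
                for cls, val in rec.per_class[clf].items():
                    row[f"mcc_{cls}"] = val
                rows.append(row)
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def stratified_folds(labels: Sequence[str], k: int, seed: int) -> np.ndarray:
    """Fold id (0..k-1) per sample; class-stratified, deterministic.

    Samples are shuffled within each class, concatenated class by class,
    and dealt round-robin, so fold sizes differ by at most one and every
    class is spread as evenly as its size allows.
    """
    n = len(labels)
    if k < 2:
        raise ValidationError(f"need at least 2 folds, got {k}")
    if k > n:
        raise ValidationError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    labels_arr = np.asarray(labels)
    folds = np.empty(n, dtype=np.int64)
    position = 0
    for c in dict.fromkeys(labels):
        members = rng.permutation(np.flatnonzero(labels_arr == c))
        for idx in members:
            folds[idx] = position % k
            position += 1
    return folds


def kfold_cv(
    dataset: ExpressionDataset,
    spec: ClassifierSpec,
    k: int,
    seed: int,
    folds: np.ndarray | None = None,
) -> ConfusionMatrix:
    """Pooled k-fold cross-validation confusion matrix.

    Each sample is predicted exactly once, by the model trained on the
    folds it does not belong to; all out-of-fold predictions are pooled
    into one confusion matrix over the dataset's class vocabulary.
    """
    if folds is None:
        folds = stratified_folds(dataset.labels, k, seed)
    folds = np.asarray(folds)
    if folds.shape != (dataset.n_samples,):
        raise ValidationError("fold assignment does not match the dataset")
    predicted: list[str | None] = [None] * dataset.n_samples
    for f in range(k):
        test_idx = np.flatnonzero(folds == f)
        if test_idx.size == 0:
            continue
        train_idx = np.flatnonzero(folds != f)
        model = train(spec, dataset.subset_rows(train_idx))
        for i, lab in zip(test_idx, predict(model, dataset.subset_rows(test_idx))):
            predicted[i] = lab
    assert all(p is not None for p in predicted)
    return confusion(dataset.labels, predicted, dataset.classes)  # type: ignore[arg-type]


def run_ifs(
    dataset: ExpressionDataset,
    ranked: RankedFeatureList,
    specs: Sequence[ClassifierSpec],
    k: int = 10,
    seed: int = 0,
    max_features: int | None = None,
) -> IFSCurve:
    """Evaluate every ranked-prefix feature set with every classifier spec.

    ``max_features`` caps the curve length (defaults to the full ranking).
    The fold assignment is computed once and shared across all prefixes and
    classifiers.
    """
    if set(ranked.ordered) != set(dataset.feature_names):
        raise ValidationError("ranked list does not cover the dataset's features")
    cap = len(ranked.ordered) if max_features is None else int(max_features)
    if cap < 1:
        raise ValidationError(f"max_features must be >= 1, got {max_features}")
    cap = min(cap, len(ranked.ordered))
    names = [s.algorithm for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError("classifier specs must have distinct algorithms")
    if not specs:
        raise ValidationError("at least one classifier spec required")

    folds = stratified_folds(dataset.labels, k, seed)
    records = []
    for i in range(1, cap + 1):
        sub = dataset.select_features(ranked.top(i))
        overall: dict[str, float] = {}
        per_class: dict[str, dict[str, float]] = {}
        for spec in specs:
            cm = kfold_cv(sub, spec, k, seed, folds=folds)
            overall[spec.algorithm] = multiclass_mcc(cm)
            per_class[spec.algorithm] = {
                cls: per_class_mcc(cm, j) for j, cls in enumerate(cm.classes)
            }
        records.append(IFSRecord(feature_count=i, overall=overall, per_class=per_class))
    return IFSCurve(records=tuple(records), ranked=ranked, cv_folds=k, seed=seed)


def select_optimal(
    curve: IFSCurve,
    classifier: str,
    policy: str = "first_above",
    threshold: float = 0.9,
) -> int:
    """Pick the optimal feature count from an IFS curve.

    ``first_above``: the smallest prefix whose MCC reaches ``threshold``
    (parsimony rule), falling back to ``argmax`` when the curve never gets
    there.  ``argmax``: the smallest prefix attaining the curve's maximum.
    """
    series = curve.mcc_series(classifier)
    if not series:
        raise ValidationError("empty IFS curve")
    if policy == "first_above":
        for count, mcc in series:
            if mcc >= threshold:
                return count
        policy = "argmax"
    if policy == "argmax":
        best = max(m for _, m in series)
        return min(count for count, m in series if m == best)
    raise ValidationError(f"unknown selection policy {policy!r}")


def evaluate_final(
    train_set: ExpressionDataset,
    test_set: ExpressionDataset,
    features: Sequence[str],
    spec: ClassifierSpec,
) -> tuple[ConfusionMatrix, float, dict[str, float]]:
    """Train once on the full training set (restricted to the selected
    panel) and evaluate once on the held-out test set."""
    if len(features) == 0:
        raise ValidationError("the selected feature panel is empty")
    tr = train_set.select_features(features)
    te = test_set.select_features(features)
    model: TrainedModel = train(spec, tr)
    predicted = predict(model, te)
    cm = confusion(te.labels, predicted, model.classes)
    per_cls = {cls: per_class_mcc(cm, j) for j, cls in enumerate(cm.classes)}
    return cm, multiclass_mcc(cm), per_cls


def plot_curve(curve: IFSCurve, path: str | Path) -> None:
    """Write the feature-count vs MCC curve (one line per classifier)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for clf in curve.classifiers():
        pts = curve.mcc_series(clf)
        ax.plot([p[0] for p in pts], [p[1] for p in pts], label=clf, linewidth=1.2)
    ax.set_xlabel("number of top-ranked features")
    ax.set_ylabel(f"multiclass MCC ({curve.cv_folds}-fold CV, pooled)")
    ax.set_ylim(-0.05, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
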