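"""The four classification algorithms behind one train/predict contract.

* ``svm_smo`` — support vector machine: one binary SVM per class pair
  (quadratic program solved by scikit-learn's libsvm backend, an SMO-type
  solver) combined by one-vs-one pairwise voting; features standardized to
  training mean/SD.  Linear kernel, C = 1 by default.
* ``ib1`` — 1-nearest-neighbor with normalized Euclidean distance: each
  feature min-max scaled to [0, 1] by its training extremes (a zero-range
  feature contributes 0 to every distance); distance ties go to the
  earliest training sample.
* ``dagging`` — an ensemble of one base learner trained on k disjoint,
  class-stratified subsamples of the training set, combined by majority
  vote (ties to the earliest class in the vocabulary).
* ``random_forest`` — bagged decision trees with sqrt(p) features per
  split (scikit-learn), 100 trees by default.

All algorithms are deterministic given the spec's seed.  Class vocabulary
order is the order of first appearance in the training labels, and every
tie-break refers to that order.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from itertools import combinations
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .dataset import ExpressionDataset
from .errors import ValidationError

__all__ = [
    "ALGORITHMS",
    "ClassifierSpec",
    "TrainedModel",
    "train",
    "predict",
    "ib1_nearest",
    "dagging_partition",
    "majority_vote",
]

ALGORITHMS = ("svm_smo", "ib1", "dagging", "random_forest")


@dataclass(frozen=True)
class ClassifierSpec:
    """Algorithm choice plus hyperparameters.

    Recognized hyperparameters: ``svm_smo``: ``C`` (default 1.0), ``kernel``
    (default ``"linear"``); ``dagging``: ``k`` (subset count, default 10),
    ``base`` (a ClassifierSpec, default svm_smo); ``random_forest``:
    ``n_trees`` (default 100), ``max_features`` (default ``"sqrt"``);
    ``ib1``: none.
    """

    algorithm: str
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        object.__setattr__(self, "hyperparameters", dict(self.hyperparameters))
        if self.algorithm == "dagging":
            base = self.hyperparameters.get("base")
            if base is not None:
                if not isinstance(base, ClassifierSpec):
                    raise ValidationError("dagging base must be a ClassifierSpec")
                if base.algorithm == "dagging":
                    raise ValidationError("dagging cannot use dagging as its base learner")

    def hp(self, name: str, default: Any) -> Any:
        return self.hyperparameters.get(name, default)


@dataclass(frozen=True)
class TrainedModel:
    """A fitted classifier bound to its training feature set and vocabulary."""

    spec: ClassifierSpec
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    _impl: Any = field(repr=False)

    def predict_matrix(self, x: np.ndarray) -> np.ndarray:
        """Class indices for a matrix whose columns match ``feature_names``."""
        return self._impl(x)


# ---------------------------------------------------------------------------
# svm_smo: standardization + one-vs-one pairwise voting


class _PairwiseSVM:
    def __init__(self, x: np.ndarray, y: np.ndarray, n_classes: int, c: float, kernel: str, seed: int):
        self.mean = x.mean(axis=0)
        sd = x.std(axis=0)
        self.scale = np.where(sd > 0, sd, 1.0)
        xs = (x - self.mean) / self.scale
        self.n_classes = n_classes
        self.models: dict[tuple[int, int], SVC] = {}
        for a, b in combinations(range(n_classes), 2):
            mask = (y == a) | (y == b)
            svc = SVC(C=c, kernel=kernel, random_state=seed)
            svc.fit(xs[mask], y[mask])
            self.models[(a, b)] = svc

    def __call__(self, x: np.ndarray) -> np.ndarray:
        xs = (x - self.mean) / self.scale
        votes = np.zeros((x.shape[0], self.n_classes), dtype=np.int64)
        for (a, b), svc in self.models.items():
            pred = svc.predict(xs)
            for cls in (a, b):
                votes[:, cls] += pred == cls
        # argmax returns the first maximum: ties go to the earliest class
        return votes.argmax(axis=1)


# ---------------------------------------------------------------------------
# ib1: min-max normalized 1-NN


class _IB1:
    def __init__(self, x: np.ndarray, y: np.ndarray):
        self.lo = x.min(axis=0)
        rng = x.max(axis=0) - self.lo
        self.inv = np.where(rng > 0, 1.0 / np.where(rng > 0, rng, 1.0), 0.0)
        self.xs = (x - self.lo) * self.inv
        self.y = y

    def __call__(self, x: np.ndarray) -> np.ndarray:
        xs = (x - self.lo) * self.inv
        out = np.empty(x.shape[0], dtype=np.int64)
        # chunked to bound memory on large probe sets
        step = max(1, 2_000_000 // max(1, self.xs.shape[0]))
        for start in range(0, xs.shape[0], step):
            block = xs[start : start + step]
            d2 = ((block[:, None, :] - self.xs[None, :, :]) ** 2).sum(axis=2)
            out[start : start + step] = self.y[d2.argmin(axis=1)]
        return out


# ---------------------------------------------------------------------------
# dagging


class _Dagging:
    def __init__(self, voters: list[TrainedModel], classes: tuple[str, ...]):
        self.voters = voters
        self.classes = classes

    def __call__(self, x: np.ndarray) -> np.ndarray:
        pos = {c: k for k, c in enumerate(self.classes)}
        n_classes = len(self.classes)
        counts = np.zeros((x.shape[0], n_classes), dtype=np.int64)
        for voter in self.voters:
            # map each voter's own vocabulary into the ensemble's
            local = np.asarray([pos[c] for c in voter.classes], dtype=np.int64)
            pred = local[voter.predict_matrix(x)]
            counts[np.arange(x.shape[0]), pred] += 1
        # first maximum: ties go to the earliest class in the vocabulary
        return counts.argmax(axis=1)


class _Forest:
    def __init__(self, forest: RandomForestClassifier):
        self.forest = forest

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forest.predict(x)


def dagging_partition(
    n: int, k: int, seed: int, labels: Sequence[str] | None = None
) -> list[np.ndarray]:
    """k disjoint index sets of size floor(n/k) each (so k*n' <= n).

    With ``labels`` given, the subsets are class-stratified: samples are
    shuffled within each class, concatenated class by class, and dealt
    round-robin so every class spreads as evenly as its size allows.
    Deterministic given ``seed``.
    """
    if k < 1:
        raise ValidationError(f"subset count k must be >= 1, got {k}")
    if k > n:
        raise ValidationError(f"cannot build {k} disjoint subsets from {n} samples")
    rng = np.random.default_rng(seed)
    if labels is None:
        seq = rng.permutation(n)
    else:
        labels_arr = np.asarray(labels)
        if labels_arr.size != n:
            raise ValidationError("labels length must equal n")
        seq = np.concatenate(
            [
                rng.permutation(np.flatnonzero(labels_arr == c))
                for c in dict.fromkeys(labels)
            ]
        )
    size = n // k
    # deal positions round-robin, keep the first n' dealt into each subset
    subsets: list[list[int]] = [[] for _ in range(k)]
    for pos, idx in enumerate(seq):
        bucket = subsets[pos % k]
        if len(bucket) < size:
            bucket.append(int(idx))
    return [np.sort(np.asarray(b, dtype=np.intp)) for b in subsets]


def majority_vote(votes: Sequence[str], vocabulary: Sequence[str] | None = None) -> str:
    """Most frequent label; ties resolved to the earliest vocabulary entry."""
    if len(votes) == 0:
        raise ValidationError("majority_vote needs at least one vote")
    vocab = list(vocabulary) if vocabulary is not None else list(dict.fromkeys(votes))
    counts = {v: 0 for v in vocab}
    for v in votes:
        if v not in counts:
            raise ValidationError(f"vote {v!r} outside vocabulary")
        counts[v] += 1
    return max(vocab, key=lambda v: (counts[v], -vocab.index(v)))


def train(spec: ClassifierSpec, data: ExpressionDataset) -> TrainedModel:
    """Fit a classifier; deterministic given ``spec.seed``."""
    classes = data.classes
    if len(classes) < 2:
        raise ValidationError("training needs at least two classes")
    pos = {c: k for k, c in enumerate(classes)}
    y = np.asarray([pos[lab] for lab in data.labels], dtype=np.int64)
    x = data.values

    if spec.algorithm == "svm_smo":
        impl: Any = _PairwiseSVM(
            x, y, len(classes), float(spec.hp("C", 1.0)), str(spec.hp("kernel", "linear")), spec.seed
        )
    elif spec.algorithm == "ib1":
        impl = _IB1(x, y)
    elif spec.algorithm == "random_forest":
        forest = RandomForestClassifier(
            n_estimators=int(spec.hp("n_trees", 100)),
            max_features=spec.hp("max_features", "sqrt"),
            random_state=spec.seed,
        )
        forest.fit(x, y)
        impl = _Forest(forest)
    elif spec.algorithm == "dagging":
        k = int(spec.hp("k", 10))
        if k > data.n_samples:
            raise ValidationError(f"dagging k={k} exceeds n={data.n_samples}")
        base: ClassifierSpec = spec.hp("base", ClassifierSpec("svm_smo", seed=spec.seed))
        voters = []
        for idx in dagging_partition(data.n_samples, k, spec.seed, data.labels):
            sub = data.subset_rows(idx)
            if len(sub.classes) < 2:
                continue  # a tiny subset may have collapsed to one class
            voters.append(train(base, sub))
        if not voters:
            raise ValidationError("no dagging subset retained two classes; lower k")
        impl = _Dagging(voters, classes)
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValidationError(f"unknown algorithm {spec.algorithm!r}")

    return TrainedModel(spec=spec, classes=classes, feature_names=data.feature_names, _impl=impl)


def predict(model: TrainedModel, samples: ExpressionDataset) -> tuple[str, ...]:
    """Labels for new samples; columns are matched to the model by name."""
    if samples.n_samples == 0:
        return ()
    aligned = samples.select_features(model.feature_names)
    idx = model.predict_matrix(aligned.values)
    return tuple(model.classes[i] for i in idx)


def ib1_nearest(query: Sequence[float], train_data: ExpressionDataset) -> str:
    """Label of the min-max-normalized nearest training sample to one query."""
    if train_data.n_samples == 0:
        raise ValidationError("training set is empty")
    pos = {c: k for k, c in enumerate(train_data.classes)}
    y = np.asarray([pos[lab] for lab in train_data.labels], dtype=np.int64)
    nn = _IB1(train_data.values, y)
    q = np.asarray(query, dtype=np.float64).reshape(1, -1)
    if q.shape[1] != train_data.n_features:
        raise ValidationError(
            f"query has {q.shape[1]} values, training data {train_data.n_features} features"
        )
    return train_data.classes[int(nn(q)[0])]
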