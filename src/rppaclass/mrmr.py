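"""Minimum-redundancy-maximum-relevance (mRMR) feature ranking.

Each expression feature is discretized into three levels around its mean
(below mean - k*sigma, within, above mean + k*sigma), mutual information is
estimated with the plug-in (maximum-likelihood) estimator in nats, and
features are ranked greedily: the first pick maximizes relevance I(f, c)
with the class label c, and every later pick maximizes

    I(f, c) - (1/m) * sum_{s in selected} I(f, s)

over the not-yet-selected features, where m is the number of already
selected features.  The ranking runs for all N features, producing a full
ordering from most to least useful.

The class label is used as-is (categorical); only expression features are
discretized.  Log base does not affect the ordering (it rescales relevance
and redundancy by the same factor); nats are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .errors import ValidationError

__all__ = [
    "DiscretizationConfig",
    "RankedFeatureList",
    "discretize_feature",
    "mutual_information",
    "relevance",
    "redundancy",
    "mrmr_rank",
]

_LEVELS = ("low", "mid", "high")

# two greedy scores closer than this are one mathematical value up to
# floating-point rounding; such ties go to the leftmost column
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class DiscretizationConfig:
    """Mean +/- k*sigma three-level binning.

    ``k_sigma`` is the half-width of the central bin in population standard
    deviations; 1 is the conventional choice for mRMR on expression data.
    """

    scheme: str = "mean_sigma"
    k_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.scheme != "mean_sigma":
            raise ValidationError(f"unknown discretization scheme: {self.scheme!r}")
        if not (np.isfinite(self.k_sigma) and self.k_sigma > 0):
            raise ValidationError(f"k_sigma must be finite and positive, got {self.k_sigma}")


def _discretize_codes(values: np.ndarray, config: DiscretizationConfig) -> np.ndarray:
    """Integer codes 0/1/2 for low/mid/high."""
    mean = values.mean()
    sd = values.std()  # population SD
    lo = mean - config.k_sigma * sd
    hi = mean + config.k_sigma * sd
    codes = np.ones(values.shape, dtype=np.int64)
    codes[values < lo] = 0
    codes[values > hi] = 2
    return codes


def discretize_feature(
    values: Sequence[float] | np.ndarray, config: DiscretizationConfig | None = None
) -> np.ndarray:
    """Map one feature vector to categorical levels ``low``/``mid``/``high``.

    ``low`` iff value < mean - k*sd, ``high`` iff value > mean + k*sd, else
    ``mid``; a constant vector (sd = 0) discretizes to all ``mid``.
    """
    config = config or DiscretizationConfig()
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError("values must be a non-empty 1-D vector")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("values must be finite")
    return np.asarray(_LEVELS, dtype=object)[_discretize_codes(arr, config)]


def _encode(x: Sequence) -> np.ndarray:
    return np.unique(np.asarray(x), return_inverse=True)[1]


def _mi_codes(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI (nats) of two integer-coded vectors."""
    kx = int(x.max()) + 1
    ky = int(y.max()) + 1
    joint = np.bincount(x * ky + y, minlength=kx * ky).astype(np.float64)
    joint = joint.reshape(kx, ky) / x.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def mutual_information(x: Sequence, y: Sequence) -> float:
    """Plug-in mutual information (nats) between two categorical vectors."""
    xa, ya = np.asarray(x), np.asarray(y)
    if xa.ndim != 1 or ya.ndim != 1 or xa.size == 0:
        raise ValidationError("inputs must be non-empty 1-D vectors")
    if xa.size != ya.size:
        raise ValidationError(f"length mismatch: {xa.size} vs {ya.size}")
    return _mi_codes(_encode(xa), _encode(ya))


def relevance(feature: Sequence, labels: Sequence) -> float:
    """I(f, c): mutual information of a discretized feature with the class."""
    return mutual_information(feature, labels)


def redundancy(feature: Sequence, selected: Sequence[Sequence]) -> float:
    """Mean MI of a feature with each already-selected feature."""
    if len(selected) == 0:
        raise ValidationError("redundancy is undefined for an empty selected set")
    return float(np.mean([mutual_information(feature, s) for s in selected]))


@dataclass(frozen=True)
class RankedFeatureList:
    """The full mRMR ordering with per-step scores.

    ``scores[h]`` is the greedy objective value at which ``ordered[h]`` was
    selected (pure relevance for the first pick, relevance minus mean
    redundancy afterwards); ``relevance_`` maps every feature to I(f, c).
    """

    ordered: tuple[str, ...]
    scores: tuple[float, ...]
    relevance_: dict[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.ordered) != len(self.scores):
            raise ValidationError("ordered and scores lengths differ")
        if set(self.ordered) != set(self.relevance_):
            raise ValidationError("relevance_ keys must match ordered features")

    def top(self, i: int) -> tuple[str, ...]:
        return self.ordered[:i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ordered) + 1),
                "feature": list(self.ordered),
                "objective": list(self.scores),
                "relevance": [self.relevance_[f] for f in self.ordered],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RankedFeatureList":
        frame = frame.sort_values("rank")
        return cls(
            ordered=tuple(frame["feature"].astype(str)),
            scores=tuple(frame["objective"].astype(float)),
            relevance_=dict(
                zip(frame["feature"].astype(str), frame["relevance"].astype(float))
            ),
        )


def mrmr_rank(
    dataset: ExpressionDataset, config: DiscretizationConfig | None = None
) -> RankedFeatureList:
    """Greedy mRMR ranking of all features of a dataset.

    Deterministic: ties in the objective (scores within 1e-12, i.e. equal
    up to rounding) are broken by original column order, leftmost wins.
    Zero-variance features discretize to all-mid, carry zero MI with
    everything, and sink to the bottom ranks.
    """
    config = config or DiscretizationConfig()
    if dataset.n_features < 1:
        raise ValidationError("dataset has no features")
    labels = _encode(dataset.labels)
    if labels.max() == 0:
        raise ValidationError("mRMR needs at least two distinct class labels")

    n_feat = dataset.n_features
    codes = np.empty((n_feat, dataset.n_samples), dtype=np.int64)
    for j in range(n_feat):
        codes[j] = _discretize_codes(dataset.values[:, j], config)

    rel = np.array([_mi_codes(codes[j], labels) for j in range(n_feat)])

    remaining = list(range(n_feat))
    order: list[int] = []
    scores: list[float] = []
    red_sum = np.zeros(n_feat)  # sum of MI(f, s) over selected s, per feature

    while remaining:
        if not order:
            objective = {j: rel[j] for j in remaining}
        else:
            m = len(order)
            objective = {j: rel[j] - red_sum[j] / m for j in remaining}
        # leftmost column wins ties; scores within _TIE_TOL count as tied so
        # that mathematically equal candidates are not separated by rounding
        best = remaining[0]
        for j in remaining[1:]:
            if objective[j] > objective[best] + _TIE_TOL:
                best = j
        order.append(best)
        scores.append(objective[best])
        remaining.remove(best)
        if remaining:
            for j in remaining:
                red_sum[j] += _mi_codes(codes[j], codes[best])

    names = dataset.feature_names
    return RankedFeatureList(
        ordered=tuple(names[j] for j in order),
        scores=tuple(float(s) for s in scores),
        relevance_={names[j]: float(rel[j]) for j in range(n_feat)},
    )
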