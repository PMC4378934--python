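"""Synthetic RPPA-like datasets with known informative/redundant/noise structure.

The generator emulates the shape of a pan-cancer RPPA cohort: a handful of
unbalanced tumor-type classes, a real-valued expression matrix, and three
kinds of features:

* *informative* — Gaussian with a class-specific mean; class means sit on a
  seeded +/-``effect_size/2`` sign grid so every pair of classes differs in
  expectation on at least one informative feature, and the within-class
  standard deviation is 1 (so ``effect_size`` is the between-class mean
  separation in within-class SD units);
* *redundant* — a jittered copy of one informative feature (source feature
  plus ``N(0, redundancy_noise_sd^2)`` noise), emulating antibodies that
  track the same signal;
* *noise* — standard Gaussian, independent of the class label.

The default specification mirrors the 10-class, 187-protein cohort this
pipeline targets, scaled to ~500 samples with class proportions matching
the real cohort's tumor-type frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .errors import ValidationError

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "default_spec",
    "all_noise_spec",
    "TUMOR_TYPE_SIZES",
]

# Tumor-type sample counts of the reference pan-cancer RPPA cohort
# (10 classes after merging the two colorectal types, 3467 samples).
TUMOR_TYPE_SIZES: dict[str, int] = {
    "BLCA": 127,
    "BRCA": 747,
    "COAD/READ": 464,
    "GBM": 215,
    "HNSC": 212,
    "KIRC": 454,
    "LUAD": 237,
    "LUSC": 195,
    "OV": 412,
    "UCEC": 404,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic cohort."""

    class_sizes: tuple[int, ...]
    n_informative: int
    n_redundant: int
    n_noise: int
    effect_size: float = 2.0
    redundancy_noise_sd: float = 0.2
    seed: int = 0
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_sizes", tuple(int(s) for s in self.class_sizes))
        if self.class_names is not None:
            object.__setattr__(self, "class_names", tuple(self.class_names))
        if len(self.class_sizes) < 1 or any(s < 1 for s in self.class_sizes):
            raise ValidationError("class_sizes must be positive integers")
        if min(self.n_informative, self.n_redundant, self.n_noise) < 0:
            raise ValidationError("feature counts must be nonnegative")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValidationError("redundant features need informative sources")
        if self.redundancy_noise_sd < 0:
            raise ValidationError("redundancy_noise_sd must be >= 0")
        if not np.isfinite(self.effect_size):
            raise ValidationError("effect_size must be finite")
        if self.class_names is not None and len(self.class_names) != len(self.class_sizes):
            raise ValidationError("class_names and class_sizes lengths differ")

    @property
    def n_classes(self) -> int:
        return len(self.class_sizes)

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise

    @property
    def n_samples(self) -> int:
        return sum(self.class_sizes)

    def resolved_class_names(self) -> tuple[str, ...]:
        if self.class_names is not None:
            return self.class_names
        return tuple(f"class_{k + 1:02d}" for k in range(self.n_classes))


@dataclass(frozen=True)
class GroundTruth:
    """Which features carry signal, and how."""

    informative: frozenset[str]
    redundant: dict[str, str]  # redundant feature -> source informative feature
    noise: frozenset[str]
    class_means: pd.DataFrame = field(repr=False)  # classes x informative features

    def to_frame(self) -> pd.DataFrame:
        rows = [(f, "informative", "") for f in sorted(self.informative)]
        rows += [(f, "redundant", src) for f, src in sorted(self.redundant.items())]
        rows += [(f, "noise", "") for f in sorted(self.noise)]
        return pd.DataFrame(rows, columns=["feature", "role", "source"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def default_spec(seed: int = 0) -> SyntheticSpec:
    """Desk-scale default: 10 unbalanced classes (~500 samples), 187 features.

    Class sizes are the reference cohort's tumor-type proportions scaled to a
    total near 500; features split 20 informative + 20 redundant + 147 noise.
    """
    total = sum(TUMOR_TYPE_SIZES.values())
    sizes = tuple(round(n * 500 / total) for n in TUMOR_TYPE_SIZES.values())
    return SyntheticSpec(
        class_sizes=sizes,
        n_informative=20,
        n_redundant=20,
        n_noise=147,
        effect_size=2.0,
        redundancy_noise_sd=0.2,
        seed=seed,
        class_names=tuple(TUMOR_TYPE_SIZES),
    )


def _class_sign_grid(rng: np.random.Generator, n_classes: int, n_informative: int) -> np.ndarray:
    """Seeded +/-1 pattern with pairwise-distinct class rows."""
    if n_informative == 0:
        return np.zeros((n_classes, 0))
    if 2 ** n_informative < n_classes:
        raise ValidationError(
            f"{n_informative} informative features cannot separate {n_classes} classes"
        )
    for _ in range(1000):
        signs = rng.choice([-1.0, 1.0], size=(n_classes, n_informative))
        if len({tuple(row) for row in signs}) == n_classes:
            return signs
    raise ValidationError("failed to draw distinct class sign patterns")


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one cohort. Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    names_inf = tuple(f"inf_{j + 1:03d}" for j in range(spec.n_informative))
    names_red = tuple(f"red_{j + 1:03d}" for j in range(spec.n_redundant))
    names_nse = tuple(f"noise_{j + 1:03d}" for j in range(spec.n_noise))
    class_names = spec.resolved_class_names()

    signs = _class_sign_grid(rng, spec.n_classes, spec.n_informative)
    means = signs * (spec.effect_size / 2.0)

    n = spec.n_samples
    labels_idx = np.repeat(np.arange(spec.n_classes), spec.class_sizes)
    informative = means[labels_idx] + rng.standard_normal((n, spec.n_informative))

    sources = (
        np.arange(spec.n_redundant) % spec.n_informative
        if spec.n_redundant
        else np.empty(0, dtype=int)
    )
    redundant = (
        informative[:, sources] + rng.standard_normal((n, spec.n_redundant)) * spec.redundancy_noise_sd
        if spec.n_redundant
        else np.empty((n, 0))
    )
    noise = rng.standard_normal((n, spec.n_noise))

    dataset = ExpressionDataset(
        sample_ids=tuple(f"S{i + 1:04d}" for i in range(n)),
        labels=tuple(class_names[k] for k in labels_idx),
        feature_names=names_inf + names_red + names_nse,
        values=np.hstack([informative, redundant, noise]),
    )
    truth = GroundTruth(
        informative=frozenset(names_inf),
        redundant={names_red[j]: names_inf[sources[j]] for j in range(spec.n_redundant)},
        noise=frozenset(names_nse),
        class_means=pd.DataFrame(means, index=list(class_names), columns=list(names_inf)),
    )
    return dataset, truth


def all_noise_spec(spec: SyntheticSpec | None = None) -> SyntheticSpec:
    """The matching no-signal control: same shape, every feature pure noise."""
    base = spec if spec is not None else default_spec()
    return replace(
        base,
        n_informative=0,
        n_redundant=0,
        n_noise=base.n_features,
    )
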