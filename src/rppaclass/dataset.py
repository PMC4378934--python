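"""Expression-table container, delimited I/O, class merging and stratified splitting.

The native on-disk format is a UTF-8 delimited table whose header row is
``sample_id, class, <feature_1..N>`` with one sample per row: the first
column holds the sample identifier, the second the class label (the tumor
type), and every remaining column one protein's normalized expression
value.  Tab- or comma-delimited variants are both accepted; the delimiter
is inferred from the file suffix (``.csv`` means comma, anything else tab)
unless given explicitly.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "ExpressionDataset",
    "SplitResult",
    "read_dataset",
    "write_dataset",
    "merge_classes",
    "stratified_split",
    "apply_split",
    "convert_spreadsheet",
]

_ID_COL = "sample_id"
_CLASS_COL = "class"


@dataclass(frozen=True)
class ExpressionDataset:
    """A sample x protein expression matrix with class labels.

    Parameters
    ----------
    sample_ids
        Unique identifier per sample (row).
    labels
        Class name per sample, aligned with ``sample_ids``.
    feature_names
        Unique name per feature (column).
    values
        Real matrix, shape ``(n_samples, n_features)``; RPPA-normalized
        expression, unitless.
    """

    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "labels", tuple(str(c) for c in self.labels))
        object.__setattr__(self, "feature_names", tuple(str(f) for f in self.feature_names))
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValidationError(f"values must be 2-D, got shape {values.shape}")
        object.__setattr__(self, "values", values)
        n, p = values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValidationError(
                f"row mismatch: {n} value rows, {len(self.sample_ids)} sample ids, "
                f"{len(self.labels)} labels"
            )
        if len(self.feature_names) != p:
            raise ValidationError(
                f"column mismatch: {p} value columns, {len(self.feature_names)} feature names"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.feature_names)) != p:
            raise ValidationError("duplicate feature names")
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression values must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def classes(self) -> tuple[str, ...]:
        """Class vocabulary in order of first appearance."""
        return tuple(dict.fromkeys(self.labels))

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {c: 0 for c in self.classes}
        for lab in self.labels:
            counts[lab] += 1
        return counts

    def subset_rows(self, indices: Sequence[int]) -> "ExpressionDataset":
        idx = np.asarray(indices, dtype=np.intp)
        return ExpressionDataset(
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            labels=tuple(self.labels[i] for i in idx),
            feature_names=self.feature_names,
            values=self.values[idx],
        )

    def select_features(self, names: Sequence[str]) -> "ExpressionDataset":
        """Restrict to the given features, in the given order."""
        pos = {f: j for j, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in pos]
        if missing:
            raise ValidationError(f"unknown features: {missing[:5]}")
        cols = np.asarray([pos[f] for f in names], dtype=np.intp)
        return ExpressionDataset(
            sample_ids=self.sample_ids,
            labels=self.labels,
            feature_names=tuple(names),
            values=self.values[:, cols],
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.feature_names))
        frame.insert(0, _CLASS_COL, list(self.labels))
        frame.insert(0, _ID_COL, list(self.sample_ids))
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionDataset":
        if frame.shape[1] < 3:
            raise ParseError("table needs sample-id, class, and >=1 feature column")
        ids = frame.iloc[:, 0].astype(str)
        labels = frame.iloc[:, 1].astype(str)
        feat = frame.iloc[:, 2:]
        numeric = np.empty(feat.shape, dtype=np.float64)
        for j, col in enumerate(feat.columns):
            parsed = pd.to_numeric(feat[col], errors="coerce")
            bad = parsed.index[parsed.isna() & feat[col].notna()]
            if len(bad) > 0:
                raise ParseError(
                    f"non-numeric expression value at sample {ids.loc[bad[0]]!r}, "
                    f"feature {col!r}: {feat[col].loc[bad[0]]!r}"
                )
            if parsed.isna().any():
                miss = parsed.index[parsed.isna()][0]
                raise ParseError(
                    f"missing expression value at sample {ids.loc[miss]!r}, feature {col!r}"
                )
            numeric[:, j] = parsed.to_numpy()
        return cls(
            sample_ids=tuple(ids),
            labels=tuple(labels),
            feature_names=tuple(str(c) for c in feat.columns),
            values=numeric,
        )


@dataclass(frozen=True)
class SplitResult:
    """A train/test partition of one dataset."""

    train: ExpressionDataset
    test: ExpressionDataset
    assignment: tuple[str, ...]  # "train" / "test" per input sample, input order
    seed: int

    def to_frame(self) -> pd.DataFrame:
        # Train and test keep the input's relative row order, so zipping the
        # assignment flags against the two id streams recovers input order.
        it_train = iter(self.train.sample_ids)
        it_test = iter(self.test.sample_ids)
        rows = [
            (next(it_train) if flag == "train" else next(it_test), flag)
            for flag in self.assignment
        ]
        return pd.DataFrame(rows, columns=[_ID_COL, "partition"])


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_dataset(path: str | Path, delimiter: str | None = None) -> ExpressionDataset:
    """Read a delimited expression table.

    Layout contract: first column sample ID, second column class label,
    remaining columns protein expression values (finite reals).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such dataset file: {path}")
    if path.stat().st_size == 0:
        raise ParseError(f"empty dataset file: {path}")
    frame = pd.read_csv(path, sep=_delimiter_for(path, delimiter), dtype=str)
    if frame.shape[0] == 0:
        raise ParseError(f"dataset file has a header but no data rows: {path}")
    return ExpressionDataset.from_frame(frame)


def write_dataset(
    dataset: ExpressionDataset, path: str | Path, delimiter: str | None = None
) -> None:
    """Write a dataset so that :func:`read_dataset` reproduces it exactly."""
    if dataset.n_features == 0:
        raise ValidationError("refusing to write a dataset with no features")
    path = Path(path)
    dataset.to_frame().to_csv(
        path, sep=_delimiter_for(path, delimiter), index=False, encoding="utf-8"
    )


def merge_classes(
    dataset: ExpressionDataset, mapping: Mapping[str, str]
) -> ExpressionDataset:
    """Rename class labels, e.g. ``{"COAD": "COAD/READ", "READ": "COAD/READ"}``.

    Samples, features and values are untouched; only labels change.
    """
    present = set(dataset.labels)
    unknown = sorted(set(mapping) - present)
    if unknown:
        raise ValidationError(f"mapping references labels absent from the dataset: {unknown}")
    return ExpressionDataset(
        sample_ids=dataset.sample_ids,
        labels=tuple(mapping.get(lab, lab) for lab in dataset.labels),
        feature_names=dataset.feature_names,
        values=dataset.values,
    )


def _round_half_down(x: float) -> int:
    """Nearest integer, exact .5 resolved downward."""
    return math.ceil(x - 0.5)


def stratified_split(
    dataset: ExpressionDataset, test_fraction: float, seed: int
) -> SplitResult:
    """Class-stratified random train/test split.

    Per-class test counts are ``round-half-down(class_size * test_fraction)``;
    if their sum misses the rounded global test size, the largest classes are
    corrected by one sample each until the totals agree, so the overall split
    is exact and reproducible for a given seed.
    """
    if not (0.0 <= test_fraction < 1.0):
        raise ValidationError(f"test_fraction must be in [0, 1), got {test_fraction}")
    counts = dataset.class_counts()
    if any(c < 1 for c in counts.values()):
        raise ValidationError("every class needs at least one sample")

    per_class = {c: _round_half_down(n * test_fraction) for c, n in counts.items()}
    target = _round_half_down(dataset.n_samples * test_fraction)
    by_size = sorted(counts, key=lambda c: (-counts[c], dataset.classes.index(c)))
    i = 0
    while sum(per_class.values()) != target and by_size:
        c = by_size[i % len(by_size)]
        step = 1 if sum(per_class.values()) < target else -1
        if 0 <= per_class[c] + step <= counts[c]:
            per_class[c] += step
        i += 1

    rng = np.random.default_rng(seed)
    labels = np.asarray(dataset.labels)
    is_test = np.zeros(dataset.n_samples, dtype=bool)
    for c in dataset.classes:
        members = np.flatnonzero(labels == c)
        picked = rng.permutation(members)[: per_class[c]]
        is_test[picked] = True

    train_idx = np.flatnonzero(~is_test)
    test_idx = np.flatnonzero(is_test)
    return SplitResult(
        train=dataset.subset_rows(train_idx),
        test=dataset.subset_rows(test_idx),
        assignment=tuple("test" if t else "train" for t in is_test),
        seed=seed,
    )


def apply_split(
    dataset: ExpressionDataset, membership: Mapping[str, str]
) -> SplitResult:
    """Consume a precomputed train/test membership (sample id -> partition).

    Used when the source distribution already fixes the split, instead of
    re-splitting at random.
    """
    missing = [s for s in dataset.sample_ids if s not in membership]
    if missing:
        raise ValidationError(f"membership missing for samples: {missing[:5]}")
    flags = []
    for s in dataset.sample_ids:
        part = membership[s]
        if part not in ("train", "test"):
            raise ValidationError(f"partition for {s!r} must be 'train' or 'test', got {part!r}")
        flags.append(part)
    is_test = np.asarray([f == "test" for f in flags])
    return SplitResult(
        train=dataset.subset_rows(np.flatnonzero(~is_test)),
        test=dataset.subset_rows(np.flatnonzero(is_test)),
        assignment=tuple(flags),
        seed=-1,
    )


def convert_spreadsheet(
    xlsx_path: str | Path, out_path: str | Path, delimiter: str | None = None
) -> list[Path]:
    """One-shot converter: spreadsheet -> native delimited table(s).

    Each sheet must follow the same column layout as the text format
    (sample id, class, then expression columns).  A single sheet becomes one
    table; with multiple sheets each sheet ``<name>`` becomes
    ``<out stem>.<name><out suffix>``, so a workbook that encodes the
    train/test membership as separate sheets converts losslessly.
    """
    xlsx_path = Path(xlsx_path)
    out_path = Path(out_path)
    sheets = pd.read_excel(xlsx_path, sheet_name=None, dtype=str)
    written: list[Path] = []
    if len(sheets) == 1:
        frame = next(iter(sheets.values()))
        write_dataset(ExpressionDataset.from_frame(frame), out_path, delimiter)
        written.append(out_path)
    else:
        for name, frame in sheets.items():
            target = out_path.with_name(f"{out_path.stem}.{name}{out_path.suffix}")
            write_dataset(ExpressionDataset.from_frame(frame), target, delimiter)
            written.append(target)
    return written
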