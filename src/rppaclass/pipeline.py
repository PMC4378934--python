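"""End-to-end orchestration: split -> rank -> IFS -> select -> final test.

A run takes either a delimited expression table or a synthetic-cohort
specification, holds out a stratified test partition, ranks features by
mRMR on the training partition only, traces the IFS curve with k-fold CV,
selects the optimal panel, and only then trains the final model and
touches the test partition once.  Every artifact (ranking, curve, panel,
confusion matrices, metrics, resolved configuration and a JSON summary)
is written to the output directory, and the whole run is deterministic
given its seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .classifiers import ClassifierSpec
from .dataset import (
    ExpressionDataset,
    apply_split,
    merge_classes,
    read_dataset,
    stratified_split,
)
from .errors import ValidationError
from .ifs import evaluate_final, plot_curve, run_ifs, select_optimal
from .metrics import multiclass_mcc, per_class_mcc
from .mrmr import DiscretizationConfig, mrmr_rank
from .simulate import SyntheticSpec, generate

__all__ = ["PipelineConfig", "run_pipeline", "config_from_yaml"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; exactly one input source must be set."""

    outdir: str | Path
    input_path: str | Path | None = None
    synthetic: SyntheticSpec | None = None
    class_merge: Mapping[str, str] | None = None
    membership_path: str | Path | None = None  # precomputed train/test table
    test_fraction: float = 0.2
    split_seed: int = 0
    k_sigma: float = 1.0
    classifiers: tuple[ClassifierSpec, ...] = (ClassifierSpec("svm_smo"),)
    final_classifier: str = "svm_smo"
    cv_folds: int = 10
    cv_seed: int = 0
    policy: str = "first_above"
    threshold: float = 0.9
    max_features: int | None = None
    write_plot: bool = False

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValidationError("exactly one of input_path / synthetic must be given")
        if self.final_classifier not in {s.algorithm for s in self.classifiers}:
            raise ValidationError(
                f"final classifier {self.final_classifier!r} is not among the curve classifiers"
            )


def _resolved_config(config: PipelineConfig) -> dict[str, Any]:
    def plain(value: Any) -> Any:
        if dataclasses.is_dataclass(value) and not isinstance(value, type):
            return {f.name: plain(getattr(value, f.name)) for f in dataclasses.fields(value)}
        if isinstance(value, Path):
            return str(value)
        if isinstance(value, Mapping):
            return {k: plain(v) for k, v in value.items()}
        if isinstance(value, (list, tuple, set, frozenset)):
            return [plain(v) for v in value]
        return value

    return {"version": __version__, **plain(config)}  # type: ignore[arg-type]


def _load_input(config: PipelineConfig) -> ExpressionDataset:
    if config.input_path is not None:
        dataset = read_dataset(config.input_path)
    else:
        dataset, _ = generate(config.synthetic)
    if config.class_merge:
        dataset = merge_classes(dataset, dict(config.class_merge))
    return dataset


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full workflow; returns the summary also written to disk."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict[str, Any]:
    with open(outdir / "resolved_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(_resolved_config(config), fh, sort_keys=False)

    dataset = _load_input(config)
    logger.info(
        "input: %d samples, %d features, %d classes",
        dataset.n_samples,
        dataset.n_features,
        len(dataset.classes),
    )

    if config.membership_path is not None:
        import pandas as pd

        table = pd.read_csv(config.membership_path, sep=None, engine="python", dtype=str)
        split = apply_split(dataset, dict(zip(table.iloc[:, 0], table.iloc[:, 1])))
        logger.info("split: precomputed membership from %s", config.membership_path)
    else:
        split = stratified_split(dataset, config.test_fraction, config.split_seed)
        logger.info(
            "split: stratified, fraction=%s seed=%d", config.test_fraction, config.split_seed
        )
    split.to_frame().to_csv(outdir / "split.tsv", sep="\t", index=False)
    train_set, test_set = split.train, split.test
    test_ids = set(test_set.sample_ids)
    # test-set isolation: feature selection and the IFS curve see train only
    assert test_ids.isdisjoint(train_set.sample_ids)

    ranked = mrmr_rank(train_set, DiscretizationConfig(k_sigma=config.k_sigma))
    ranked.write(outdir / "ranking.tsv")
    logger.info("mRMR ranking of %d features done", len(ranked.ordered))

    curve = run_ifs(
        train_set,
        ranked,
        config.classifiers,
        k=config.cv_folds,
        seed=config.cv_seed,
        max_features=config.max_features,
    )
    curve.write(outdir / "ifs_curve.tsv")
    if config.write_plot:
        plot_curve(curve, outdir / "ifs_curve.png")

    panel_size = select_optimal(
        curve, config.final_classifier, policy=config.policy, threshold=config.threshold
    )
    panel = list(ranked.top(panel_size))
    (outdir / "panel.txt").write_text("\n".join(panel) + "\n", encoding="utf-8")
    logger.info("selected panel: %d features (%s policy)", panel_size, config.policy)

    train_rec = next(r for r in curve.records if r.feature_count == panel_size)
    train_cv_mcc = train_rec.overall[config.final_classifier]

    final_spec = next(s for s in config.classifiers if s.algorithm == config.final_classifier)
    cm_test, test_mcc, test_per_class = evaluate_final(train_set, test_set, panel, final_spec)
    assert set(cm_test.classes) <= set(dataset.classes)
    cm_test.to_frame().to_csv(outdir / "confusion_test.tsv", sep="\t")

    metrics_rows = [("multiclass_mcc_train_cv", "", train_cv_mcc), ("multiclass_mcc_test", "", test_mcc)]
    metrics_rows += [
        ("per_class_mcc_train_cv", cls, val)
        for cls, val in train_rec.per_class[config.final_classifier].items()
    ]
    metrics_rows += [("per_class_mcc_test", cls, val) for cls, val in test_per_class.items()]
    import pandas as pd

    pd.DataFrame(metrics_rows, columns=["metric", "class", "value"]).to_csv(
        outdir / "metrics.tsv", sep="\t", index=False
    )

    summary: dict[str, Any] = {
        "n_samples": dataset.n_samples,
        "n_features": dataset.n_features,
        "n_classes": len(dataset.classes),
        "n_train": train_set.n_samples,
        "n_test": test_set.n_samples,
        "final_classifier": config.final_classifier,
        "selection_policy": config.policy,
        "panel_size": panel_size,
        "panel": panel,
        "train_cv_mcc": train_cv_mcc,
        "test_mcc": test_mcc,
        "per_class_test_mcc": test_per_class,
        "curve_max_mcc": {
            clf: max(m for _, m in curve.mcc_series(clf)) for clf in curve.classifiers()
        },
    }
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("train-CV MCC %.4f, test MCC %.4f", train_cv_mcc, test_mcc)
    return summary


def _spec_from_mapping(entry: Mapping[str, Any] | str, seed: int) -> ClassifierSpec:
    if isinstance(entry, str):
        return ClassifierSpec(entry, seed=seed)
    entry = dict(entry)
    algorithm = entry.pop("algorithm")
    spec_seed = int(entry.pop("seed", seed))
    base = entry.pop("base", None)
    if base is not None:
        entry["base"] = _spec_from_mapping(base, seed)
    return ClassifierSpec(algorithm, hyperparameters=entry, seed=spec_seed)


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a plain key-value YAML file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    seed = int(raw.get("seed", 0))
    synthetic = None
    if "synthetic" in raw:
        syn = dict(raw["synthetic"])
        syn.setdefault("seed", seed)
        if "class_sizes" in syn:
            syn["class_sizes"] = tuple(syn["class_sizes"])
        if "class_names" in syn and syn["class_names"] is not None:
            syn["class_names"] = tuple(syn["class_names"])
        synthetic = SyntheticSpec(**syn)
    classifiers: Sequence[Any] = raw.get("classifiers", ["svm_smo"])
    specs = tuple(_spec_from_mapping(entry, seed) for entry in classifiers)
    return PipelineConfig(
        outdir=raw["outdir"],
        input_path=raw.get("input_path"),
        synthetic=synthetic,
        class_merge=raw.get("class_merge"),
        membership_path=raw.get("membership_path"),
        test_fraction=float(raw.get("test_fraction", 0.2)),
        split_seed=int(raw.get("split_seed", seed)),
        k_sigma=float(raw.get("k_sigma", 1.0)),
        classifiers=specs,
        final_classifier=raw.get("final_classifier", specs[0].algorithm),
        cv_folds=int(raw.get("cv_folds", 10)),
        cv_seed=int(raw.get("cv_seed", seed)),
        policy=raw.get("policy", "first_above"),
        threshold=float(raw.get("threshold", 0.9)),
        max_features=(None if raw.get("max_features") is None else int(raw["max_features"])),
        write_plot=bool(raw.get("write_plot", False)),
    )
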