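import math
from collections import Counter

import numpy as np
import pytest

from rppaclass import (
    ClassifierSpec,
    ExpressionDataset,
    ValidationError,
    confusion,
    multiclass_mcc,
    predict,
    train,
)
from rppaclass.classifiers import dagging_partition, ib1_nearest, majority_vote
from rppaclass.simulate import SyntheticSpec, generate

from conftest import ALL_SPECS


class TestSpecValidation:
    def test_unknown_algorithm(self):
        with pytest.raises(ValidationError):
            ClassifierSpec("perceptron")

    def test_dagging_cannot_nest_dagging(self):
        with pytest.raises(ValidationError):
            ClassifierSpec("dagging", {"base": ClassifierSpec("dagging")})

    def test_single_class_training_rejected(self, toy_separable):
        single = toy_separable.subset_rows(range(10))
        with pytest.raises(ValidationError):
            train(ClassifierSpec("ib1"), single)


@pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.algorithm)
class TestAllAlgorithms:
    def test_separable_training_set_is_learned(self, spec, toy_separable):
        model = train(
            ClassifierSpec(spec.algorithm, {"k": 4} if spec.algorithm == "dagging" else {}, seed=0),
            toy_separable,
        )
        assert predict(model, toy_separable) == toy_separable.labels

    def test_determinism_given_seed(self, spec, small_cohort):
        ds, _ = small_cohort
        p1 = predict(train(spec, ds), ds)
        p2 = predict(train(spec, ds), ds)
        assert p1 == p2

    def test_feature_columns_matched_by_name(self, spec, toy_separable):
        model = train(
            ClassifierSpec(spec.algorithm, {"k": 4} if spec.algorithm == "dagging" else {}, seed=0),
            toy_separable,
        )
        swapped = toy_separable.select_features(("f2", "f1"))
        assert predict(model, swapped) == predict(model, toy_separable)

    def test_perfect_mcc_on_widely_separated_classes(self, spec):
        gen_spec = SyntheticSpec(
            class_sizes=(15, 15, 15), n_informative=4, n_redundant=0, n_noise=0,
            effect_size=10.0, seed=21,
        )
        ds, _ = generate(gen_spec)
        train_ds = ds.subset_rows(range(0, 45, 2))
        test_ds = ds.subset_rows(range(1, 45, 2))
        clf = ClassifierSpec(spec.algorithm, {"k": 4} if spec.algorithm == "dagging" else {}, seed=21)
        cm = confusion(test_ds.labels, predict(train(clf, train_ds), test_ds), train_ds.classes)
        assert multiclass_mcc(cm) == pytest.approx(1.0)


class TestPredictContract:
    def test_empty_probe_set(self, toy_separable):
        model = train(ClassifierSpec("ib1"), toy_separable)
        empty = toy_separable.subset_rows([])
        assert predict(model, empty) == ()

    def test_missing_feature_rejected(self, toy_separable):
        model = train(ClassifierSpec("ib1"), toy_separable)
        probe = toy_separable.select_features(("f1",))
        with pytest.raises(ValidationError):
            predict(model, probe)

    @pytest.mark.parametrize("algorithm", ["svm_smo", "ib1"])
    def test_row_order_does_not_change_predictions(self, algorithm, small_cohort):
        ds, _ = small_cohort
        rng = np.random.default_rng(4)
        shuffled = ds.subset_rows(rng.permutation(ds.n_samples))
        probe = ds.subset_rows(range(0, ds.n_samples, 3))
        p1 = predict(train(ClassifierSpec(algorithm, seed=0), ds), probe)
        p2 = predict(train(ClassifierSpec(algorithm, seed=0), shuffled), probe)
        assert p1 == p2


class TestIB1:
    def test_training_sample_is_its_own_neighbor(self, small_cohort):
        ds, _ = small_cohort
        model = train(ClassifierSpec("ib1"), ds)
        assert predict(model, ds) == ds.labels

    def test_normalization_hand_example(self):
        """After min-max scaling the query (0.6, 50) maps to (0.6, 0.5);
        distances are sqrt(0.61)=0.781 to A and sqrt(0.41)=0.640 to B."""
        train_ds = ExpressionDataset(
            ("a", "b"), ("A", "B"), ("f1", "f2"), np.array([[0.0, 0.0], [1.0, 100.0]])
        )
        assert ib1_nearest([0.6, 50.0], train_ds) == "B"
        # the scaled distances themselves
        assert math.sqrt(0.6**2 + 0.5**2) == pytest.approx(0.781, abs=5e-4)
        assert math.sqrt(0.4**2 + 0.5**2) == pytest.approx(0.640, abs=5e-4)

    def test_constant_feature_contributes_nothing(self):
        train_ds = ExpressionDataset(
            ("a", "b"), ("A", "B"), ("flat", "f2"), np.array([[7.0, 0.0], [7.0, 1.0]])
        )
        assert ib1_nearest([1e6, 0.1], train_ds) == "A"

    def test_distance_tie_goes_to_earliest_sample(self):
        train_ds = ExpressionDataset(
            ("a", "b"), ("A", "B"), ("f1",), np.array([[0.0], [1.0]])
        )
        assert ib1_nearest([0.5], train_ds) == "A"


class TestDaggingPartition:
    def test_exact_division(self):
        parts = dagging_partition(10, 5, seed=0)
        assert len(parts) == 5
        assert all(len(p) == 2 for p in parts)
        assert sorted(np.concatenate(parts)) == list(range(10))

    def test_inexact_division_leaves_remainder_unused(self):
        parts = dagging_partition(10, 3, seed=0)
        assert all(len(p) == 3 for p in parts)
        assert len(np.concatenate(parts)) == 9

    def test_singleton_boundary(self):
        parts = dagging_partition(4, 4, seed=1)
        assert all(len(p) == 1 for p in parts)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValidationError):
            dagging_partition(3, 5, seed=0)

    @pytest.mark.parametrize("n,k", [(17, 3), (50, 7), (23, 23), (100, 10)])
    def test_disjoint_and_sized(self, n, k):
        parts = dagging_partition(n, k, seed=5)
        flat = np.concatenate(parts)
        assert len(flat) == len(set(flat.tolist())) == k * (n // k)
        assert all(len(p) == n // k for p in parts)

    def test_stratified_when_labels_given(self):
        labels = ["A"] * 20 + ["B"] * 20
        parts = dagging_partition(40, 4, seed=2, labels=labels)
        for p in parts:
            classes = [labels[i] for i in p]
            assert set(classes) == {"A", "B"}
            assert abs(classes.count("A") - classes.count("B")) <= 1


class TestMajorityVote:
    def test_simple_majority(self):
        assert majority_vote(["A", "A", "B"]) == "A"

    def test_tie_goes_to_vocabulary_order(self):
        assert majority_vote(["A", "B"], vocabulary=("A", "B")) == "A"
        assert majority_vote(["A", "B"], vocabulary=("B", "A")) == "B"

    def test_empty_votes_rejected(self):
        with pytest.raises(ValidationError):
            majority_vote([])

    def test_agrees_with_exhaustive_tally(self):
        rng = np.random.default_rng(6)
        vocab = ("X", "Y", "Z")
        for _ in range(100):
            votes = [vocab[i] for i in rng.integers(0, 3, size=7)]
            counts = Counter(votes)
            top = max(counts.values())
            expected = next(v for v in vocab if counts.get(v, 0) == top)
            assert majority_vote(votes, vocabulary=vocab) == expected


class TestDagging:
    def test_k1_equals_base_learner(self, small_cohort):
        ds, _ = small_cohort
        base = ClassifierSpec("svm_smo", seed=3)
        dag = ClassifierSpec("dagging", {"k": 1, "base": base}, seed=3)
        probe = ds.subset_rows(range(0, ds.n_samples, 2))
        # with k=1 the single subset is the whole training set (n' = n)
        assert predict(train(dag, ds), probe) == predict(train(base, ds), probe)

    def test_k_exceeding_n_rejected(self, toy_separable):
        with pytest.raises(ValidationError):
            train(ClassifierSpec("dagging", {"k": 100}), toy_separable)
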