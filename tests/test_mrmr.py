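"""mRMR unit tests, checked against independent brute-force oracles."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import mutual_info_score

from rppaclass import ExpressionDataset, ValidationError
from rppaclass.mrmr import (
    DiscretizationConfig,
    discretize_feature,
    mrmr_rank,
    mutual_information,
    redundancy,
    relevance,
)

from conftest import random_dataset

# --- independent oracles -----------------------------------------------------


def oracle_mi(x, y):
    """Plug-in MI from explicit joint/marginal frequency tables (nats)."""
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        pab = c / n
        total += pab * math.log(pab / ((px[a] / n) * (py[b] / n)))
    return total


def oracle_entropy(x):
    n = len(x)
    return -sum((c / n) * math.log(c / n) for c in Counter(x).values())


def oracle_discretize(values, k=1.0):
    mean = np.mean(values)
    sd = np.std(values)
    return [
        "low" if v < mean - k * sd else ("high" if v > mean + k * sd else "mid")
        for v in values
    ]


def oracle_greedy_mrmr(dataset, k=1.0):
    """Plain-python greedy ranking, written independently of the package."""
    disc = {
        f: oracle_discretize(dataset.values[:, j], k)
        for j, f in enumerate(dataset.feature_names)
    }
    labels = list(dataset.labels)
    rel = {f: oracle_mi(disc[f], labels) for f in dataset.feature_names}
    remaining = list(dataset.feature_names)
    selected = []
    while remaining:
        best, best_score = None, None
        for f in remaining:  # leftmost wins ties (scores equal up to 1e-12)
            if selected:
                red = sum(oracle_mi(disc[f], disc[s]) for s in selected) / len(selected)
                score = rel[f] - red
            else:
                score = rel[f]
            if best_score is None or score > best_score + 1e-12:
                best, best_score = f, score
        selected.append(best)
        remaining.remove(best)
    return selected


# --- discretization ----------------------------------------------------------


class TestDiscretize:
    def test_constant_vector_is_all_mid(self):
        out = discretize_feature([3.0] * 5)
        assert list(out) == ["mid"] * 5

    def test_hand_example_mean_sigma(self):
        # mean 0, population sd 2: thresholds at -2 and 2
        out = discretize_feature([-3, -1, 0, 1, 3], DiscretizationConfig(k_sigma=1.0))
        assert list(out) == ["low", "mid", "mid", "mid", "high"]

    def test_huge_k_is_all_mid(self):
        out = discretize_feature([-5.0, 0.0, 7.0], DiscretizationConfig(k_sigma=1e9))
        assert list(out) == ["mid"] * 3

    def test_empty_vector_rejected(self):
        with pytest.raises(ValidationError):
            discretize_feature([])

    def test_agrees_with_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.normal(size=rng.integers(2, 40))
            k = float(rng.uniform(0.3, 2.0))
            assert list(discretize_feature(v, DiscretizationConfig(k_sigma=k))) == oracle_discretize(v, k)


# --- mutual information ------------------------------------------------------


class TestMutualInformation:
    def test_self_information_equiprobable_binary(self):
        x = [0, 0, 1, 1]
        assert mutual_information(x, x) == pytest.approx(math.log(2), abs=1e-12)

    def test_independent_table_is_zero(self):
        assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_six_sample_joint_histogram(self):
        x = [0, 0, 1, 1, 1, 1]
        y = [0, 1, 0, 0, 1, 1]
        assert mutual_information(x, y) == pytest.approx(oracle_mi(x, y), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mutual_information([0, 1], [0, 1, 1])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.integers(0, 3), min_size=1, max_size=30),
        st.data(),
    )
    def test_symmetry_bounds_and_oracle(self, x, data):
        y = data.draw(st.lists(st.integers(0, 3), min_size=len(x), max_size=len(x)))
        mi = mutual_information(x, y)
        assert mi >= -1e-15
        assert mutual_information(y, x) == pytest.approx(mi, abs=1e-12)
        assert mi <= min(oracle_entropy(x), oracle_entropy(y)) + 1e-12
        assert mi == pytest.approx(oracle_mi(x, y), abs=1e-12)

    def test_matches_sklearn_plug_in_estimator(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.integers(0, 4, size=50)
            y = rng.integers(0, 3, size=50)
            assert mutual_information(x, y) == pytest.approx(
                mutual_info_score(x, y), abs=1e-12
            )


class TestRelevanceRedundancy:
    def test_relevance_of_label_copy_is_label_entropy(self):
        labels = ["A", "A", "B", "C"]
        assert relevance(labels, labels) == pytest.approx(oracle_entropy(labels), abs=1e-12)

    def test_relevance_separates_informative_from_noise(self, default_cohort):
        ds, truth = default_cohort
        best_noise = max(
            relevance(discretize_feature(ds.values[:, ds.feature_names.index(f)]), ds.labels)
            for f in sorted(truth.noise)[:30]
        )
        for f in sorted(truth.informative)[:5]:
            rel = relevance(discretize_feature(ds.values[:, ds.feature_names.index(f)]), ds.labels)
            assert rel > best_noise

    def test_redundancy_with_self_is_entropy(self):
        x = [0, 1, 1, 2, 2, 2]
        assert redundancy(x, [x]) == pytest.approx(oracle_entropy(x), abs=1e-12)

    def test_redundancy_is_mean_of_pairwise_mi(self):
        rng = np.random.default_rng(1)
        f = list(rng.integers(0, 3, size=30))
        sel = [list(rng.integers(0, 3, size=30)) for _ in range(3)]
        expected = np.mean([oracle_mi(f, s) for s in sel])
        assert redundancy(f, sel) == pytest.approx(expected, abs=1e-12)

    def test_empty_selected_rejected(self):
        with pytest.raises(ValidationError):
            redundancy([0, 1], [])


# --- greedy ranking ----------------------------------------------------------


class TestMrmrRank:
    def test_single_feature(self):
        ds = ExpressionDataset(("a", "b"), ("A", "B"), ("f0",), np.array([[0.0], [1.0]]))
        ranked = mrmr_rank(ds)
        assert ranked.ordered == ("f0",)

    def test_single_class_rejected(self):
        ds = ExpressionDataset(("a", "b"), ("A", "A"), ("f0",), np.array([[0.0], [1.0]]))
        with pytest.raises(ValidationError):
            mrmr_rank(ds)

    def test_output_is_permutation(self, small_cohort):
        ds, _ = small_cohort
        ranked = mrmr_rank(ds)
        assert sorted(ranked.ordered) == sorted(ds.feature_names)
        assert ranked.scores[0] == max(ranked.relevance_.values())

    def test_first_pick_maximizes_relevance(self, small_cohort):
        ds, _ = small_cohort
        ranked = mrmr_rank(ds)
        assert ranked.relevance_[ranked.ordered[0]] == max(ranked.relevance_.values())

    @pytest.mark.parametrize("trial", range(40))
    def test_agrees_with_brute_force_greedy(self, trial):
        rng = np.random.default_rng(1000 + trial)
        ds = random_dataset(
            rng,
            n_samples=int(rng.integers(10, 51)),
            n_features=int(rng.integers(2, 9)),
            n_classes=int(rng.integers(2, 4)),
        )
        assert list(mrmr_rank(ds).ordered) == oracle_greedy_mrmr(ds)

    def test_duplicate_of_rank1_not_rank2(self):
        """A verbatim copy of the top feature is fully redundant and must
        lose rank 2 to any independent feature with positive relevance."""
        rng = np.random.default_rng(3)
        n = 200
        labels = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        strong = np.where(labels == "A", 0.0, 5.0) + rng.normal(0, 0.3, n)
        weak = np.where(labels == "A", 0.0, 1.0) + rng.normal(0, 1.0, n)
        ds = ExpressionDataset(
            tuple(f"s{i}" for i in range(n)),
            tuple(labels),
            ("strong", "dup", "weak"),
            np.column_stack([strong, strong.copy(), weak]),
        )
        ranked = mrmr_rank(ds)
        assert ranked.ordered[0] == "strong"
        assert ranked.ordered[1] == "weak"

    def test_ranking_round_trips_through_table(self, tmp_path, small_cohort):
        from rppaclass.mrmr import RankedFeatureList
        import pandas as pd

        ds, _ = small_cohort
        ranked = mrmr_rank(ds)
        path = tmp_path / "ranking.tsv"
        ranked.write(path)
        back = RankedFeatureList.from_frame(pd.read_csv(path, sep="\t"))
        assert back.ordered == ranked.ordered
        assert back.scores == pytest.approx(ranked.scores)
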