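import numpy as np
import pytest

from rppaclass import ClassifierSpec, ExpressionDataset
from rppaclass.simulate import SyntheticSpec, default_spec, generate


@pytest.fixture(scope="session")
def default_cohort():
    """The desk-scale default synthetic cohort (10 classes, 187 features)."""
    return generate(default_spec(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 3-class cohort with strong signal for classifier checks."""
    spec = SyntheticSpec(
        class_sizes=(30, 30, 30),
        n_informative=5,
        n_redundant=2,
        n_noise=8,
        effect_size=4.0,
        seed=7,
    )
    return generate(spec)


@pytest.fixture()
def toy_separable():
    """Two widely separated 2-D classes, trivially separable."""
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 0.1, size=(10, 2))
    b = rng.normal(5.0, 0.1, size=(10, 2))
    values = np.vstack([a, b])
    return ExpressionDataset(
        sample_ids=tuple(f"s{i}" for i in range(20)),
        labels=("A",) * 10 + ("B",) * 10,
        feature_names=("f1", "f2"),
        values=values,
    )


def random_dataset(rng, n_samples, n_features, n_classes):
    """Unstructured random dataset (>= 2 classes) for oracle comparisons."""
    labels = rng.integers(n_classes, size=n_samples)
    labels[0], labels[1] = 0, 1  # guarantee at least two classes
    return ExpressionDataset(
        sample_ids=tuple(f"s{i}" for i in range(n_samples)),
        labels=tuple(str(c) for c in labels),
        feature_names=tuple(f"f{j}" for j in range(n_features)),
        values=rng.normal(size=(n_samples, n_features)),
    )


ALL_SPECS = [ClassifierSpec(a, seed=11) for a in ("svm_smo", "ib1", "dagging", "random_forest")]
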