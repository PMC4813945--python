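import numpy as np
import pytest

from mtraining import (EnsembleConfig, LabeledSet, UnlabeledSet, evaluate_split,
                       study_benchmark)
from mtraining.base import ClassifierSpec


def make_labeled(n_per_class=20, n_classes=3, n_features=4, sep=6.0, seed=0,
                 labels=("a", "b", "c", "d", "e"), id_prefix=""):
    """Well-separated Gaussian blobs as a LabeledSet."""
    rng = np.random.default_rng(seed)
    X, y, ids = [], [], []
    for k in range(n_classes):
        mean = np.zeros(n_features)
        mean[k % n_features] = sep * (1 + k // n_features)
        X.append(rng.normal(mean, 1.0, size=(n_per_class, n_features)))
        y.extend([labels[k]] * n_per_class)
        ids.extend(f"{id_prefix}{labels[k]}{j}" for j in range(n_per_class))
    return LabeledSet(np.array(ids, dtype=object), np.vstack(X), np.array(y, dtype=object))


def make_unlabeled(n=30, n_features=4, seed=1, prefix="u"):
    rng = np.random.default_rng(seed)
    return UnlabeledSet(np.array([f"{prefix}{j}" for j in range(n)], dtype=object),
                        rng.normal(0.0, 3.0, size=(n, n_features)))


@pytest.fixture(scope="session")
def separable_pool():
    return make_labeled()


@pytest.fixture(scope="session")
def benchmark_sweep():
    """20-seed default-benchmark sweep at unlabeled rate 0.5, M = 4,
    shared across the statistical acceptance checks."""
    reports = []
    for seed in range(20):
        split = study_benchmark(seed=seed, unlabeled_rate=0.5)
        cfg = EnsembleConfig(M=4, seed=seed)
        reports.append(evaluate_split(split, cfg))
    return reports


@pytest.fixture
def nc_spec():
    return ClassifierSpec("nearest_centroid")
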