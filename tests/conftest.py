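import numpy as np
import pytest

from plasticlust import ExpressionDataset


@pytest.fixture
def two_cluster_toy():
    """Two well-separated Gaussian clusters on feature 1, 9 noise features."""
    rng = np.random.default_rng(42)
    n_half = 10
    f1 = np.concatenate([rng.normal(0.0, 0.3, n_half), rng.normal(6.0, 0.3, n_half)])
    noise = rng.normal(0.0, 1.0, (2 * n_half, 9))
    values = np.column_stack([f1, noise])
    labels = np.array([1] * n_half + [2] * n_half)
    ds = ExpressionDataset(
        values=values,
        feature_names=[f"p{j}" for j in range(10)],
        sample_ids=[f"s{i}" for i in range(2 * n_half)],
        ages=np.linspace(0.1, 70, 2 * n_half),
    )
    return ds, labels


@pytest.fixture
def planted_outlier_toy():
    """30 samples in 3 planted clusters plus 3 extreme outliers."""
    rng = np.random.default_rng(7)
    centers = np.array([[0.0, 0.0, 0.0, 0.0], [5.0, 5.0, 0.0, 0.0], [0.0, 5.0, 5.0, 0.0]])
    rows, labels = [], []
    for c in range(3):
        rows.append(centers[c] + rng.normal(0, 0.4, (10, 4)))
        labels += [c + 1] * 10
    outliers = rng.normal(0, 0.4, (3, 4)) + np.array([[30.0, -25.0, 28.0, -30.0]])
    values = np.vstack(rows + [outliers])
    labels = np.array(labels + [0, 0, 0])  # 0 marks planted outliers
    ds = ExpressionDataset(
        values=values,
        feature_names=[f"p{j}" for j in range(4)],
        sample_ids=[f"s{i}" for i in range(33)],
        ages=np.linspace(0.1, 75, 33),
    )
    return ds, labels


@pytest.fixture(scope="session")
def lifespan_default():
    """One default synthetic lifespan dataset shared across tests."""
    from plasticlust import generate_lifespan_dataset

    return generate_lifespan_dataset(seed=123)
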