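import numpy as np
import pytest

import qsarbench as qb


@pytest.fixture(scope="session")
def small_table():
    """Balanced 3-class table with clear signal, z-scored."""
    spec = qb.SyntheticSpec(
        n_classes=3, n_per_class=(40, 40, 40), n_descriptors=20,
        n_informative=10, class_separation=5.0, latent_dim=6, seed=42,
    )
    return qb.zscore_standardize(qb.generate_dataset(spec))


@pytest.fixture(scope="session")
def imbalanced_table():
    spec = qb.SyntheticSpec(
        n_classes=3, n_per_class=(50, 35, 25), n_descriptors=15,
        n_informative=8, class_separation=4.0, latent_dim=5, seed=7,
    )
    return qb.generate_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_prediction_set(rng, n=60, k=3, quality=2.0):
    """Random prediction set whose score quality is tunable (0 = noise)."""
    classes = np.array([f"c{i}" for i in range(k)])
    true = classes[rng.integers(k, size=n)]
    scores = rng.normal(size=(n, k))
    for j, c in enumerate(classes):
        scores[true == c, j] += quality
    predicted = classes[scores.argmax(axis=1)]
    return qb.PredictionSet(true, predicted, scores, classes)
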