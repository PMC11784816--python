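import numpy as np
import pytest

from qgafs import FeatureGenSpec, gen_features
from qgafs.selection import FeatureMatrix


@pytest.fixture(scope="session")
def separable_matrix() -> FeatureMatrix:
    """Well-separated 3-class Gaussian matrix: a linear probe scores ~1."""
    return gen_features(
        FeatureGenSpec(n=300, d=12, k=6, n_classes=3, delta=4.0, sigma=1.0, seed=42)
    )


@pytest.fixture(scope="session")
def two_class_matrix() -> FeatureMatrix:
    """Perfectly separable 2-class matrix with some noise columns."""
    rng = np.random.default_rng(7)
    n = 200
    y = np.arange(n) % 2
    X = rng.normal(size=(n, 6))
    X[:, 0] += 6.0 * y  # one dominant informative column
    informative = np.zeros(6, dtype=bool)
    informative[0] = True
    return FeatureMatrix(values=X, labels=y, informative_mask=informative)
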