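import numpy as np
import pytest

from imbcv import Dataset, NullDesign, generate_null_dataset


@pytest.fixture
def imbalanced_data() -> Dataset:
    """100 samples, 10 minority, 3 features of null Gaussian noise."""
    return generate_null_dataset(NullDesign(n=100, p=3, minority_fraction=0.1, seed=123))


@pytest.fixture
def tiny_minority_data() -> Dataset:
    """Only 2 minority samples — the degenerate end for SMOTE."""
    rng = np.random.default_rng(5)
    features = rng.normal(size=(12, 2))
    labels = np.array([1, 1] + [0] * 10)
    return Dataset(features, labels)
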