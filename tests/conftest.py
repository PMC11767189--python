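import numpy as np
import pytest

from discopad.types import FeatureMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_features(values, prefix="f") -> FeatureMatrix:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return FeatureMatrix(
        values,
        [f"s{i + 1}" for i in range(n)],
        [f"{prefix}{j + 1}" for j in range(m)],
    )


@pytest.fixture
def small_features(rng):
    return make_features(rng.standard_normal((50, 4)))


def orthonormal_features(n: int, m: int) -> FeatureMatrix:
    """Mean-centered columns that are exactly orthogonal (DCT-like basis),
    so the sample Pearson correlation matrix is the identity to fp."""
    i = np.arange(n)
    cols = [np.cos(np.pi * (i + 0.5) * (k + 1) / n) for k in range(m)]
    x = np.column_stack(cols)
    x -= x.mean(axis=0)
    return make_features(x)
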