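import numpy as np
import pytest

from metsizer import SpectralMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_pilot():
    """The two-group worked example: group1 (1,2,3), group2 (4,5,6)."""
    X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
    return SpectralMatrix(X=X, groups=np.array([1, 1, 1, 2, 2, 2]))


@pytest.fixture
def gaussian_pilot(rng):
    """10 samples x 20 iid standard-normal bins, balanced groups."""
    X = rng.standard_normal((10, 20))
    return SpectralMatrix(X=X, groups=np.repeat([1, 2], 5))
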