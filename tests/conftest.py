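import numpy as np
import pytest

from gpsc import KernelParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_params():
    return KernelParams(sigma2=2.0, b=0.7, tau2=0.05)


@pytest.fixture
def five_point_data():
    """Small fixed dataset for linear-algebra oracle comparisons."""
    X = np.array(
        [
            [0.1, 0.2],
            [0.4, 0.9],
            [0.7, 0.3],
            [0.2, 0.6],
            [0.9, 0.8],
        ]
    )
    Y = np.array([1.0, -0.5, 0.3, 2.0, -1.2])
    return X, Y
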