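import numpy as np
import pytest

from markovtest import TrainOptions, simulate_ar1_gauss


@pytest.fixture
def fast_opts():
    """Short Adam schedule for unit tests where fit quality is not the point."""
    return TrainOptions(lr=1e-2, epochs=150, patience=25, seed=0)


@pytest.fixture
def ar1_series():
    return simulate_ar1_gauss(400, 0.5, seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
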