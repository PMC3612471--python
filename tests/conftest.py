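import numpy as np
import pytest

from bjel import CensoredRegressionData
from bjel.simulate import SimulationModelSpec, generate


@pytest.fixture
def toy4() -> CensoredRegressionData:
    """Four-subject sample with one censored observation.

    At beta = 1 the residuals are (0, 0.2, -0.2, 0.1) with the censored
    subject holding the smallest residual, so every hand computation
    (product-limit fit, tail mean, estimating function) is tractable.
    """
    return CensoredRegressionData(
        X=np.array([0.0, 1.0, 2.0, 3.0]),
        Z=np.array([0.0, 1.2, 1.8, 3.1]),
        delta=np.array([1, 1, 0, 1]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231)


def make_model_data(model="A", n=100, cr=0.3, seed=0):
    spec = SimulationModelSpec(model, n, cr, seed=seed)
    data, true_beta = generate(spec, np.random.default_rng(seed))
    return data, true_beta


@pytest.fixture
def model_a_small():
    """One model-A draw, n=80, 30% target censoring."""
    return make_model_data("A", n=80, cr=0.3, seed=7)


def random_censored_sample(rng, n=None, p=1, allow_ties=False):
    """A small random censored sample for property tests."""
    if n is None:
        n = int(rng.integers(p + 3, 25))
    if allow_ties:
        v = rng.integers(0, 6, n).astype(float)
    else:
        v = rng.normal(0.0, 1.0, n)
    d = rng.integers(0, 2, n)
    if d.sum() == 0:
        d[int(rng.integers(0, n))] = 1
    return v, d
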