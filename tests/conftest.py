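import numpy as np
import pytest
from hypothesis import settings

from ivcrr import DGPConfig, IVData, generate_dataset, toy_fixture

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def allzero():
    return toy_fixture("allzero")


@pytest.fixture
def twopoint():
    return toy_fixture("twopoint")


@pytest.fixture
def balanced4():
    return toy_fixture("balanced4")


@pytest.fixture
def skew3():
    return toy_fixture("skew3")


@pytest.fixture(scope="session")
def strong_dataset():
    """Strong-instrument dataset: rho2 = 0.5, n = 50,000, beta1 = 0.2."""
    return generate_dataset(DGPConfig(n=50_000, rho2=0.5, beta0=-3.0, beta1=0.2, seed=42))


def random_small_dataset(rng, n=50, ensure_events=True):
    """A small arbitrary dataset for stability / equivariance properties."""
    g = rng.normal(0, 1, n)
    x = rng.normal(0, 1, n)
    y = (rng.random(n) < 0.4).astype(int)
    if ensure_events and y.sum() == 0:
        y[0] = 1
    return IVData(g, x, y)
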