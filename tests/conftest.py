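import numpy as np
import pandas as pd
import pytest

import hydrosar as h


@pytest.fixture(scope="session")
def panel():
    """The bundled 16-sample hydrolysate panel."""
    return h.bundled_dataset()


@pytest.fixture(scope="session")
def zscales(panel):
    return panel.zscales


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_xy(rng):
    """A well-conditioned random regression instance (10 samples × 4)."""
    X = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
    beta = np.array([1.5, -2.0, 0.5, 0.0])
    y = pd.Series(X.to_numpy() @ beta + 0.1 * rng.normal(size=10), name="y")
    return X, y


@pytest.fixture(scope="session")
def benchmark():
    return h.make_benchmark()
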