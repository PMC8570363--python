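import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helper

import gecco


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_euclid(rng):
    X = rng.normal(size=(6, 2))
    return gecco.make_view(X, "euclidean")


@pytest.fixture
def tiny_manhattan(rng):
    X = rng.normal(size=(6, 2)) + 1.0
    return gecco.make_view(X, "manhattan")


@pytest.fixture
def tiny_graph():
    def build(views, kappa=3):
        return gecco.default_graph(views, kappa=min(kappa, views[0].n - 1))

    return build
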