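import numpy as np
import pytest

from sbcfw_isorank.network_io import Network
from sbcfw_isorank.product_operator import build_product_operator
from sbcfw_isorank import testkit


@pytest.fixture
def triangle() -> Network:
    return Network.from_edges(["a", "b", "c"], [(0, 1), (1, 2), (2, 0)])


@pytest.fixture
def path3() -> Network:
    return Network.from_edges(["a", "b", "c"], [(0, 1), (1, 2)])


@pytest.fixture
def p3xk3_op(path3, triangle):
    """Path (query) against triangle (target): N = 9, d = [2,2,2,4,4,4,2,2,2]."""
    return build_product_operator(path3, triangle, alpha=1.0)


@pytest.fixture
def small_planted():
    """A 4-node query planted in a 12-node target with a similarity table."""
    target = testkit.random_connected_graph(12, 4.0, seed=5)
    inst = testkit.plant_query(target, 4, rewire_fraction=0.0, seed=6)
    testkit.synth_similarity(inst, signal=1.0, noise_pairs=3, seed=7)
    return inst


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
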