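import numpy as np
import pytest

from cascadist import (
    Network,
    ModelConfig,
    build_response,
    path,
    star,
)


@pytest.fixture
def icm_config():
    return ModelConfig("icm", {"p": 0.2})


@pytest.fixture
def tm_config():
    return ModelConfig("threshold_normal", {"mu": 0.5, "sigma": 0.5})


@pytest.fixture
def two_node_tree():
    return path(2)


@pytest.fixture
def star3():
    return star(3)


@pytest.fixture
def triangle():
    return Network(edges=[("a", "b"), ("b", "c"), ("c", "a")])


def responses_for(net, config):
    return {n: build_response(config, n, net.degree(n)) for n in net.nodes}


@pytest.fixture
def make_responses():
    return responses_for


def local_maxima(probs):
    """Indices of strict-left / weak-right local maxima of a pmf."""
    p = np.asarray(probs)
    out = []
    for i in range(len(p)):
        left_ok = i == 0 or p[i] > p[i - 1]
        right_ok = i == len(p) - 1 or p[i] >= p[i + 1]
        if left_ok and right_ok and p[i] > 0:
            out.append(i)
    return out
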