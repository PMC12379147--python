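import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eddc import Graph, toy_network

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy() -> Graph:
    return toy_network()


@pytest.fixture
def path4() -> Graph:
    return Graph([(1, 2), (2, 3), (3, 4)])


@pytest.fixture
def star5() -> Graph:
    """Star on 5 nodes: center 0, leaves 1..4."""
    return Graph([(0, i) for i in range(1, 5)])


def make_er(n: int, p: float, seed: int) -> Graph:
    """Seeded ER graph built directly from binomial pair draws (test-local,
    independent of the package's generator)."""
    rng = np.random.default_rng(seed)
    edges = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return Graph(edges, nodes=range(n))
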