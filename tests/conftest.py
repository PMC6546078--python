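import numpy as np
import pytest

from ecoged.foodweb import FoodWeb


def random_web(name: str, n: int, p: float, rng: np.random.Generator) -> FoodWeb:
    """Erdős–Rényi-style directed web (self-loops included) for property tests."""
    nodes = [f"n{i:02d}" for i in range(n)]
    links = {
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(n)
        if rng.random() < p
    }
    return FoodWeb(name, nodes, links)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_pair():
    g1 = FoodWeb("g1", {"a", "b", "c"}, {("a", "b"), ("b", "c")})
    g2 = FoodWeb("g2", {"b", "c", "d"}, {("b", "c"), ("c", "d")})
    return g1, g2
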