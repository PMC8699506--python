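import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def random_graph(rng: np.random.Generator, n_max: int = 50) -> nx.Graph:
    """A random graph with integer nodes, possibly with isolates."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.0, min(1.0, 4.0 / n)))
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                G.add_edge(i, j)
    return G


@pytest.fixture
def rng():
    return np.random.default_rng(20211209)


@pytest.fixture
def tiny_lexicon():
    """The hand-checkable five-word lexicon: cat/at/cats/bat/dog."""
    from phonospread import Lexicon

    return Lexicon.from_pairs(
        [
            ("cat", ("k", "a", "t")),
            ("at", ("a", "t")),
            ("cats", ("k", "a", "t", "s")),
            ("bat", ("b", "a", "t")),
            ("dog", ("d", "o", "g")),
        ]
    )
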