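import networkx as nx
import numpy as np
import pandas as pd
import pytest

from streamnet import CountTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_table(rng):
    """10 samples x 8 taxa random count table."""
    counts = rng.integers(0, 50, size=(10, 8))
    return CountTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(10)],
            columns=[f"t{j}" for j in range(8)],
        )
    )


@pytest.fixture
def path3():
    return nx.path_graph(3)


@pytest.fixture
def star8():
    """Star with 1 hub and 7 leaves (8 nodes)."""
    return nx.star_graph(7)


def random_graph(rng, n_max=12, p=0.4):
    n = int(rng.integers(4, n_max + 1))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return g
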