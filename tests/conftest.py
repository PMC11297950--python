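import numpy as np
import pytest

from evograph.graphnet import ProteinGraph, init_parameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_graph(rng, L=6, D=4, F=3, h=5, edge_p=0.4, seed=7):
    """A small random protein graph plus matching model parameters."""
    A = (rng.random((L, L)) < edge_p).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    B = (rng.random((L, L)) < edge_p).astype(float)
    B = np.triu(B, 1)
    B = B + B.T
    g = ProteinGraph(
        features=rng.standard_normal((L, D)),
        adjacency_evc=A,
        adjacency_rc=B,
        labels=(rng.random(F) < 0.5).astype(float),
    )
    params = init_parameters(D, F, hidden=h, dropout=0.0, seed=seed)
    return g, params


@pytest.fixture
def tiny_graph(rng):
    return random_graph(rng)
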