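import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from reneel.graph import Graph


@pytest.fixture
def triangle() -> Graph:
    return Graph.from_edges(3, [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)])


@pytest.fixture
def two_triangles() -> Graph:
    """Two disconnected triangles; the unique modularity optimum is the
    two-triangle split with Q = 0.5."""
    return Graph.from_edges(6, [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0),
                                (3, 4, 1.0), (4, 5, 1.0), (3, 5, 1.0)])


def random_graph(rng: np.random.Generator, n: int, p: float = 0.4,
                 weighted: bool = False, connected: bool = False,
                 max_tries: int = 200) -> Graph:
    """Erdos-Renyi test graph; optionally weighted and/or connected."""
    iu, ju = np.triu_indices(n, k=1)
    for _ in range(max_tries):
        mask = rng.random(len(iu)) < p
        if mask.sum() == 0:
            continue
        us, vs = iu[mask], ju[mask]
        if connected:
            adj = coo_matrix((np.ones(len(us)), (us, vs)), shape=(n, n))
            ncomp, _ = connected_components(adj, directed=False)
            if ncomp != 1:
                continue
        ws = rng.uniform(0.5, 2.0, size=len(us)) if weighted else np.ones(len(us))
        return Graph.from_edges(n, ((int(u), int(v), float(w))
                                    for u, v, w in zip(us, vs, ws)))
    raise RuntimeError("could not sample graph")


def random_labels(rng: np.random.Generator, n: int, r: int) -> np.ndarray:
    """Random partition of n nodes into at most r communities."""
    return rng.integers(0, r, size=n)
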