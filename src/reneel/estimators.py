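"""scikit-learn style estimators wrapping the consensus scheme.

``RenEEL`` is the main entry point: a clusterer whose ``fit(X)`` accepts a
:class:`~reneel.graph.Graph`, a ``networkx.Graph``, or a symmetric (sparse
or dense) adjacency matrix, and exposes the consensus partition as
``labels_`` with its modularity in ``modularity_``.  ``RandomizedGreedy``
and ``NaiveEnsemble`` expose the base algorithm and the best-of-k
comparator with the same surface, and ``CoClusterSeriation`` fits the
co-clustering matrix of a partition ensemble and its annealed node order.

All estimators follow sklearn conventions: constructor stores parameters
untouched, ``fit`` validates and sets trailing-underscore attributes,
``get_params``/``set_params``/``clone`` work, and ``fit_predict`` returns
community labels.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .coclustering import SeriationConfig, anneal_order, co_cluster_matrix, seriation_cost
from .graph import Graph
from .greedy import RGConfig, naive_best, randomized_greedy
from .quality import Partition
from .scheme import run_reneel

__all__ = ["RenEEL", "RandomizedGreedy", "NaiveEnsemble", "CoClusterSeriation", "as_graph"]


def as_graph(X) -> Graph:
    """Coerce an input into a :class:`Graph`.

    Accepted: a Graph (returned as-is); a ``networkx.Graph`` (edge weights
    from the ``weight`` attribute, default 1); a symmetric dense or sparse
    adjacency matrix where ``A[u, v]`` is the edge weight and a diagonal
    entry is a self-loop of that weight.
    """
    if isinstance(X, Graph):
        return X
    try:
        import networkx as nx
    except ImportError:  # pragma: no cover
        nx = None
    if nx is not None and isinstance(X, nx.Graph):
        if X.is_directed() or X.is_multigraph():
            raise ValueError("only plain undirected networkx graphs are supported")
        nodes = list(X.nodes())
        index = {node: i for i, node in enumerate(nodes)}
        edges = ((index[u], index[v], float(d.get("weight", 1.0)))
                 for u, v, d in X.edges(data=True))
        return Graph.from_edges(len(nodes), edges, labels=nodes)
    from scipy import sparse

    if sparse.issparse(X):
        A = X.tocoo()
        n = A.shape[0]
        if A.shape[0] != A.shape[1]:
            raise ValueError("adjacency matrix must be square")
        seen = {}
        for u, v, w in zip(A.row, A.col, A.data):
            if w == 0:
                continue
            key = (int(min(u, v)), int(max(u, v)))
            if key in seen:
                if abs(seen[key] - w) > 1e-9 * max(1.0, abs(w)):
                    raise ValueError("adjacency matrix is not symmetric")
            else:
                seen[key] = float(w)
        return Graph.from_edges(n, ((u, v, w) for (u, v), w in seen.items()))
    A = np.asarray(X, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency matrix is not symmetric")
    n = A.shape[0]
    iu, ju = np.nonzero(np.triu(A))
    return Graph.from_edges(n, ((int(u), int(v), float(A[u, v])) for u, v in zip(iu, ju)))


def _seed_seq(random_state) -> np.random.SeedSequence:
    if isinstance(random_state, np.random.SeedSequence):
        return random_state
    return np.random.SeedSequence(random_state)


class RenEEL(ClusterMixin, BaseEstimator):
    """Consensus community detection by reduced-network extremal ensemble
    learning.

    Maintains an ensemble of up to ``k_max`` partitions found by randomized
    greedy agglomeration, iteratively collapses their core groups into a
    weighted reduced network, re-partitions it ``k_prime`` times, and
    updates the ensemble extremally until a single consensus partition
    remains.

    Parameters
    ----------
    k_max : int, default=100
        Ensemble capacity.
    k_prime : int, default=20
        Reduced-network partitions drawn per iteration.
    sample_size : int, default=2
        Randomized-greedy sample size per merge step.
    random_state : int or None
        Seed for all randomness; fits are deterministic given it.

    Attributes
    ----------
    labels_ : ndarray of shape (n_nodes,)
        Consensus community of each node (canonical numbering).
    modularity_ : float
        Modularity Q of the consensus partition.
    n_communities_ : int
        Number of communities in the consensus.
    n_iter_ : int
        Consensus-loop iterations executed.
    trace_ : RunTrace
        Per-iteration diagnostics (Q of best/worst/candidate, reduced
        size, ensemble size).
    """

    def __init__(self, k_max: int = 100, k_prime: int = 20, sample_size: int = 2,
                 random_state: int | None = None):
        self.k_max = k_max
        self.k_prime = k_prime
        self.sample_size = sample_size
        self.random_state = random_state

    def fit(self, X, y=None):
        g = as_graph(X)
        cfg = RGConfig(sample_size=self.sample_size)
        best, trace = run_reneel(
            g, k_max=self.k_max, k_prime=self.k_prime,
            seed=_seed_seq(self.random_state), rg_config=cfg)
        self.graph_ = g
        self.labels_ = np.asarray(best.canonical(), dtype=np.int64)
        self.modularity_ = best.q
        self.n_communities_ = best.r
        self.n_iter_ = len(trace)
        self.trace_ = trace
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class RandomizedGreedy(ClusterMixin, BaseEstimator):
    """A single randomized-greedy agglomeration run (the base algorithm)."""

    def __init__(self, sample_size: int = 2, random_state: int | None = None):
        self.sample_size = sample_size
        self.random_state = random_state

    def fit(self, X, y=None):
        g = as_graph(X)
        p = randomized_greedy(g, RGConfig(sample_size=self.sample_size),
                              seed_seq=_seed_seq(self.random_state))
        self.graph_ = g
        self.labels_ = np.asarray(p.canonical(), dtype=np.int64)
        self.modularity_ = p.q
        self.n_communities_ = p.r
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class NaiveEnsemble(ClusterMixin, BaseEstimator):
    """Best-of-k comparator: run the base algorithm ``n_runs`` times and
    keep the largest-Q partition.  Under a shared ``random_state`` its runs
    coincide with the initial ensemble of :class:`RenEEL`, making paired
    comparisons exact."""

    def __init__(self, n_runs: int = 100, sample_size: int = 2,
                 random_state: int | None = None):
        self.n_runs = n_runs
        self.sample_size = sample_size
        self.random_state = random_state

    def fit(self, X, y=None):
        g = as_graph(X)
        # mirror RenEEL's seed derivation (root -> [init, loop]) so the
        # comparator sees exactly RenEEL's initial ensemble seeds
        init_seed, _ = _seed_seq(self.random_state).spawn(2)
        p = naive_best(g, self.n_runs, RGConfig(sample_size=self.sample_size),
                       seed_seq=init_seed)
        self.graph_ = g
        self.labels_ = np.asarray(p.canonical(), dtype=np.int64)
        self.modularity_ = p.q
        self.n_communities_ = p.r
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class CoClusterSeriation(BaseEstimator):
    """Co-clustering matrix of a partition ensemble with annealed node
    order.

    ``fit`` takes a sequence of partitions (label arrays or Partition
    objects) over a common node set; ``transform`` reorders a co-clustering
    matrix by the fitted order.
    """

    def __init__(self, alpha: float = 3.0, cooling: float = 0.98,
                 steps_per_stage: int | None = None, stall_stages: int = 3,
                 t_start: float | None = None, random_state: int | None = None):
        self.alpha = alpha
        self.cooling = cooling
        self.steps_per_stage = steps_per_stage
        self.stall_stages = stall_stages
        self.t_start = t_start
        self.random_state = random_state

    def _config(self) -> SeriationConfig:
        return SeriationConfig(
            alpha=self.alpha, cooling=self.cooling,
            steps_per_stage=self.steps_per_stage, stall_stages=self.stall_stages,
            t_start=self.t_start, rng_seed=self.random_state)

    def fit(self, X: Sequence[Partition | np.ndarray], y=None):
        s = co_cluster_matrix(X)
        order = anneal_order(s, self._config())
        self.matrix_ = s
        self.order_ = order
        self.cost_ = seriation_cost(s, order, alpha=self.alpha)
        return self

    def transform(self, s: np.ndarray | None = None) -> np.ndarray:
        check_is_fitted(self, "order_")
        s = self.matrix_ if s is None else np.asarray(s)
        return s[np.ix_(self.order_, self.order_)]

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform()
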