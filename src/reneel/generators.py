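"""Synthetic graph generators for tests and demos.

Planted-partition graphs (equal-size blocks, independent Bernoulli edges
with probability ``p_in`` inside a block and ``p_out`` between blocks) and
rings of cliques (an analytic fixture whose clique-partition modularity has
a closed form) let the whole package run and be exercised without any
external network download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .graph import Graph
from .quality import Partition

__all__ = ["PlantedSpec", "planted_partition", "ring_of_cliques"]


@dataclass
class PlantedSpec:
    """Planted-partition parameters: ``blocks`` equal blocks of
    ``block_size`` nodes; within-block edge probability ``p_in`` must
    exceed the between-block ``p_out``."""
    blocks: int
    block_size: int
    p_in: float
    p_out: float
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.blocks < 1 or self.block_size < 1:
            raise ValueError("blocks and block_size must be >= 1")
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out < p_in <= 1")


def planted_partition(spec: PlantedSpec, require_connected: bool = False,
                      max_retries: int = 100, *,
                      seed_seq: np.random.SeedSequence | None = None,
                      ) -> tuple[Graph, Partition]:
    """Sample a planted-partition graph; returns (graph, planted labels).

    With ``require_connected`` the sample is redrawn until connected; a
    degenerate spec that cannot produce a usable graph within
    ``max_retries`` draws raises a ``RuntimeError``.
    """
    n = spec.blocks * spec.block_size
    block = np.repeat(np.arange(spec.blocks), spec.block_size)
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(block[iu] == block[ju], spec.p_in, spec.p_out)
    root = seed_seq if seed_seq is not None else np.random.SeedSequence(spec.rng_seed)
    rng = np.random.default_rng(root)
    for _ in range(max_retries):
        mask = rng.random(len(p)) < p
        us, vs = iu[mask], ju[mask]
        if len(us) == 0:
            continue
        if require_connected:
            adj = coo_matrix((np.ones(len(us)), (us, vs)), shape=(n, n))
            ncomp, _ = connected_components(adj, directed=False)
            if ncomp != 1:
                continue
        g = Graph.from_edges(n, ((int(u), int(v), 1.0) for u, v in zip(us, vs)))
        return g, Partition(block.copy())
    raise RuntimeError(
        f"could not sample a usable graph in {max_retries} draws; spec too sparse?")


def ring_of_cliques(K: int, c: int) -> tuple[Graph, Partition]:
    """K cliques of size c joined in a ring by single links between
    consecutive cliques.  Returns (graph, clique partition).

    Edge census: n = K*c, m = K*c*(c-1)/2 + K.
    """
    if K < 3 or c < 3:
        raise ValueError("need K >= 3 cliques of size c >= 3")
    edges = []
    for k in range(K):
        base = k * c
        for i in range(c):
            for j in range(i + 1, c):
                edges.append((base + i, base + j, 1.0))
        # link last node of clique k to first node of clique k+1
        nxt = ((k + 1) % K) * c
        edges.append((base + c - 1, nxt, 1.0))
    g = Graph.from_edges(K * c, edges)
    labels = np.repeat(np.arange(K), c)
    return g, Partition(labels)
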