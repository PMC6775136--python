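"""Exact maximum modularity by exhaustive enumeration of set partitions.

Only feasible for tiny graphs (Bell(8) = 4140, Bell(10) = 115975): used as
an independent upper-bound oracle for the stochastic algorithms.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .graph import Graph
from .quality import Partition, modularity

__all__ = ["iter_set_partitions", "q_max_exact"]


def iter_set_partitions(n: int) -> Iterator[tuple[int, ...]]:
    """All set partitions of n items as restricted-growth label strings
    (label of item 0 is 0; each label is at most 1 + max of earlier ones)."""
    labels = [0] * n

    def rec(i: int, top: int) -> Iterator[tuple[int, ...]]:
        if i == n:
            yield tuple(labels)
            return
        for c in range(top + 2):
            labels[i] = c
            yield from rec(i + 1, max(top, c))

    yield from rec(1, 0) if n > 1 else iter([tuple(labels)])


def q_max_exact(g: Graph, max_n: int = 12) -> tuple[float, Partition]:
    """Brute-force maximum modularity over all set partitions of g's nodes."""
    if g.n > max_n:
        raise ValueError(f"exhaustive search limited to n <= {max_n}, got n={g.n}")
    best_q = -np.inf
    best: tuple[int, ...] | None = None
    for labels in iter_set_partitions(g.n):
        q = modularity(g, np.asarray(labels))
        if q > best_q:
            best_q = q
            best = labels
    assert best is not None
    p = Partition(np.asarray(best))
    p.q = best_q
    return best_q, p
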