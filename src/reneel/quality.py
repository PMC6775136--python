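"""Modularity and incremental merge gains.

Modularity of a partition P = {c_1, ..., c_r} of a graph with total edge
weight m is

    Q = sum_i [ m_i / m  -  ((2 m_i + e_i) / (2 m))^2 ]

where m_i and e_i are the internal and external weight of community c_i.
Weighted graphs use weight sums throughout.  The second term equals
(s_i / 2m)^2 with s_i the summed strength of the community's nodes, which
is the form computed here (self-loops then need no special casing: a loop
of weight w adds w to m_i and 2w to s_i).

All quality values in the package flow through :func:`modularity` so that
strict floating-point comparisons between partitions are well defined: two
evaluations of the same partition produce bit-identical Q.  No epsilon is
used when the consensus loop compares Q values; an epsilon would silently
change its termination behavior.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .graph import Graph

__all__ = [
    "Partition",
    "modularity",
    "merge_delta",
    "merge_communities",
    "canonical_form",
    "community_sums",
]


def canonical_form(labels: np.ndarray | Iterable[int]) -> tuple[int, ...]:
    """Canonical label sequence: community ids renumbered by order of first
    appearance over nodes 0..n-1.  Two partitions are equal iff their
    canonical forms are identical; the tuple is hashable."""
    labels = np.asarray(list(labels) if not isinstance(labels, np.ndarray) else labels)
    _, first, inverse = np.unique(labels, return_index=True, return_inverse=True)
    # rank unique ids by first appearance
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return tuple(int(x) for x in rank[inverse])


class Partition:
    """A node partition: ``labels[v]`` is the community of node v.

    ``q`` caches the modularity on the graph the partition was scored
    against; the scheme always sets it via :func:`modularity`.
    """

    __slots__ = ("labels", "q", "_canonical")

    def __init__(self, labels: np.ndarray | Iterable[int], q: float | None = None):
        self.labels = np.asarray(labels, dtype=np.int64)
        self.q = q
        self._canonical: tuple[int, ...] | None = None

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def r(self) -> int:
        """Number of non-empty communities."""
        return len(np.unique(self.labels))

    def canonical(self) -> tuple[int, ...]:
        if self._canonical is None:
            self._canonical = canonical_form(self.labels)
        return self._canonical

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    def __repr__(self) -> str:  # pragma: no cover
        q = f", q={self.q:.6f}" if self.q is not None else ""
        return f"Partition(n={self.n}, r={self.r}{q})"


def _as_labels(p: "Partition | np.ndarray | Iterable[int]") -> np.ndarray:
    if isinstance(p, Partition):
        return p.labels
    return np.asarray(p, dtype=np.int64)


def community_sums(g: Graph, p) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-community internal weight m_i, summed strength s_i = 2 m_i + e_i,
    and the sorted array of community ids.  The shared accumulation routine
    behind every Q evaluation (index-ordered summation via ``bincount``)."""
    labels = _as_labels(p)
    if len(labels) != g.n:
        raise ValueError(f"partition covers {len(labels)} nodes, graph has {g.n}")
    ids, dense = np.unique(labels, return_inverse=True)
    u, v, w = g.edge_arrays()
    internal = dense[u] == dense[v]
    m_i = np.bincount(dense[u][internal], weights=w[internal], minlength=len(ids))
    s_i = np.bincount(dense, weights=g.strength, minlength=len(ids))
    return m_i, s_i, ids


def modularity(g: Graph, p) -> float:
    """Modularity Q of a partition; weighted graphs use weight sums."""
    m = g.require_weight()
    m_i, s_i, _ = community_sums(g, p)
    return float(m_i.sum() / m - np.sum((s_i / (2.0 * m)) ** 2))


def merge_delta(g: Graph, p, a: int, b: int) -> float:
    """Modularity change from merging communities a and b:

        dQ = 2 [ w_ab / (2m)  -  s_a s_b / (2m)^2 ]

    with w_ab the total weight between the two communities and s_x the
    summed strength of community x.  Consistent with full recomputation.
    """
    if a == b:
        raise ValueError("cannot merge a community with itself")
    labels = _as_labels(p)
    m = g.require_weight()
    m_i, s_i, ids = community_sums(g, p)
    lookup = {int(c): i for i, c in enumerate(ids)}
    if a not in lookup or b not in lookup:
        raise ValueError(f"unknown community id in ({a}, {b})")
    u, v, w = g.edge_arrays()
    lu, lv = labels[u], labels[v]
    between = ((lu == a) & (lv == b)) | ((lu == b) & (lv == a))
    w_ab = float(w[between].sum())
    s_a, s_b = s_i[lookup[a]], s_i[lookup[b]]
    two_m = 2.0 * m
    return 2.0 * (w_ab / two_m - (s_a * s_b) / (two_m * two_m))


def merge_communities(p, a: int, b: int) -> Partition:
    """Partition with communities a and b merged (b relabeled to a)."""
    labels = _as_labels(p).copy()
    labels[labels == b] = a
    return Partition(labels)
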