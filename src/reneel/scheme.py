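"""The RenEEL consensus scheme: core groups, graph reduction, extremal
ensemble updating, and the main loop.

The scheme keeps an ensemble P of at most ``k_max`` distinct partitions of
the input graph, ordered by modularity.  Each iteration:

1. finds the *core groups* — maximal node sets co-membered in every
   ensemble partition (the meet of the partitions);
2. collapses each core group to one node of a weighted *reduced network*
   G' whose self-loops carry the groups' internal weight, so that any
   partition of G' expands to a partition of G with identical Q;
3. partitions G' ``k_prime`` times with the base algorithm and expands the
   best result into a candidate partition of G;
4. updates the ensemble extremally: a candidate that is new and beats the
   worst member replaces it (at capacity) or joins the ensemble; a
   duplicate or non-improving candidate costs the ensemble its worst
   member instead.

The loop terminates when a single partition remains — the consensus.
Because candidates are unions of current core groups, core groups only
ever coarsen, the reduced network shrinks, and late iterations are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .graph import Graph
from .greedy import RGConfig, randomized_greedy
from .quality import Partition, modularity

__all__ = [
    "CoreGrouping",
    "ReducedGraph",
    "Ensemble",
    "RunTrace",
    "core_groups",
    "reduce_graph",
    "expand_partition",
    "extremal_update",
    "run_reneel",
]

#: absolute tolerance for the exact modularity-preservation identity
#: Q(G', P') == Q(G, expand(P')); violations indicate an implementation bug.
_PRESERVATION_ATOL = 1e-12


@dataclass
class CoreGrouping:
    """The meet (coarsest common refinement) of an ensemble's partitions."""
    group_of: np.ndarray            # node -> group id (dense, 0..count-1)
    groups: list[np.ndarray]        # group id -> node ids
    count: int


@dataclass
class ReducedGraph:
    """Weighted graph over core groups plus the expansion map back to the
    original nodes.  Self-loop of group g = total weight internal to g."""
    graph: Graph
    expansion: list[np.ndarray]


def core_groups(partitions: Sequence[Partition | np.ndarray]) -> CoreGrouping:
    """Core groups of an ensemble: v and w share a group iff they share a
    community in *every* partition.  Equivalently the group id is the tuple
    of a node's community ids across partitions; groups are numbered by
    first appearance in node order."""
    if len(partitions) == 0:
        raise ValueError("need at least one partition")
    rows = []
    n = None
    for p in partitions:
        lab = p.labels if isinstance(p, Partition) else np.asarray(p, dtype=np.int64)
        if n is None:
            n = len(lab)
        elif len(lab) != n:
            raise ValueError("partitions cover different node sets")
        rows.append(lab)
    key = np.stack(rows, axis=1)  # n x k
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    group_of = rank[inverse].astype(np.int64)
    count = int(group_of.max()) + 1
    groups = [np.flatnonzero(group_of == gid) for gid in range(count)]
    return CoreGrouping(group_of=group_of, groups=groups, count=count)


def reduce_graph(g: Graph, cg: CoreGrouping) -> ReducedGraph:
    """Collapse each core group to a single node; inter-group link weights
    sum, intra-group weight (including pre-existing self-loops) becomes the
    group node's self-loop.  Total weight is preserved exactly."""
    if len(cg.group_of) != g.n:
        raise ValueError("core grouping does not cover the graph")
    u, v, w = g.edge_arrays()
    gu, gv = cg.group_of[u], cg.group_of[v]
    lo = np.minimum(gu, gv)
    hi = np.maximum(gu, gv)
    # accumulate merged edge weights keyed by (lo, hi)
    key = lo * cg.count + hi
    uniq, inv = np.unique(key, return_inverse=True)
    wsum = np.bincount(inv, weights=w)
    edges = ((int(k // cg.count), int(k % cg.count), float(ww))
             for k, ww in zip(uniq, wsum))
    rg = Graph.from_edges(cg.count, edges)
    return ReducedGraph(graph=rg, expansion=list(cg.groups))


def expand_partition(rp: Partition | np.ndarray, rg: ReducedGraph) -> Partition:
    """Lift a partition of the reduced graph to the original graph: every
    original node inherits its group's community."""
    rlab = rp.labels if isinstance(rp, Partition) else np.asarray(rp, dtype=np.int64)
    if len(rlab) != rg.graph.n:
        raise ValueError("partition does not cover the reduced graph")
    n = sum(len(nodes) for nodes in rg.expansion)
    labels = np.empty(n, dtype=np.int64)
    for gid, nodes in enumerate(rg.expansion):
        labels[nodes] = rlab[gid]
    return Partition(labels)


class Ensemble:
    """Bounded, Q-ordered collection of distinct partitions of one graph.

    Members are ordered by modularity descending (best first); distinctness
    is enforced under canonical form.  Q comparisons are strict
    floating-point comparisons of values produced by the shared modularity
    routine.
    """

    def __init__(self, members: Sequence[Partition], k_max: int):
        if k_max < 1:
            raise ValueError("k_max must be >= 1")
        self.k_max = int(k_max)
        self.members: list[Partition] = []
        self._canon: set[tuple[int, ...]] = set()
        for p in members:
            if p.q is None:
                raise ValueError("ensemble members must carry a cached Q")
            key = p.canonical()
            if key in self._canon:
                continue
            self._canon.add(key)
            self.members.append(p)
        self.members.sort(key=lambda p: -p.q)
        if not 1 <= self.k <= self.k_max:
            raise ValueError(f"ensemble size {self.k} outside 1..k_max={self.k_max}")

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def best(self) -> Partition:
        return self.members[0]

    @property
    def worst(self) -> Partition:
        return self.members[-1]

    def __contains__(self, p: Partition) -> bool:
        return p.canonical() in self._canon

    def _delete_worst(self) -> None:
        gone = self.members.pop()
        self._canon.discard(gone.canonical())

    def extremal_update(self, candidate: Partition) -> str:
        """Extremal update with a candidate partition of the original graph.

        Returns an outcome tag:

        - ``"duplicate"``: candidate already in the ensemble -> worst member
          deleted, k decreases by 1;
        - ``"accepted"``: Q(candidate) > Q(worst) -> candidate inserted in
          Q-order; at capacity the worst member is removed (net replace),
          otherwise k grows by 1;
        - ``"rejected"``: otherwise (including Q ties) -> worst deleted.
        """
        if candidate.q is None:
            raise ValueError("candidate must carry a cached Q")
        if candidate in self:
            self._delete_worst()
            return "duplicate"
        if candidate.q > self.worst.q:
            if self.k == self.k_max:
                self._delete_worst()
            # insert keeping descending order; equal-Q entries keep insertion
            # after existing ones (stable)
            i = 0
            while i < self.k and self.members[i].q >= candidate.q:
                i += 1
            self.members.insert(i, candidate)
            self._canon.add(candidate.canonical())
            return "accepted"
        self._delete_worst()
        return "rejected"


def extremal_update(ens: Ensemble, candidate: Partition) -> str:
    """Functional alias for :meth:`Ensemble.extremal_update` (updates in
    place, returns the outcome tag)."""
    return ens.extremal_update(candidate)


@dataclass
class RunTrace:
    """Per-iteration diagnostics of a consensus run (post-update snapshot)."""
    iteration: list[int] = field(default_factory=list)
    q_best: list[float] = field(default_factory=list)
    q_worst: list[float] = field(default_factory=list)
    q_candidate: list[float] = field(default_factory=list)
    n_reduced: list[int] = field(default_factory=list)
    k: list[int] = field(default_factory=list)

    def append(self, iteration: int, q_best: float, q_worst: float,
               q_candidate: float, n_reduced: int, k: int) -> None:
        self.iteration.append(iteration)
        self.q_best.append(q_best)
        self.q_worst.append(q_worst)
        self.q_candidate.append(q_candidate)
        self.n_reduced.append(n_reduced)
        self.k.append(k)

    def __len__(self) -> int:
        return len(self.iteration)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "iteration": self.iteration,
            "q_best": self.q_best,
            "q_worst": self.q_worst,
            "q_candidate": self.q_candidate,
            "n_reduced": self.n_reduced,
            "k": self.k,
        })

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


BasePartitioner = Callable[[Graph, np.random.SeedSequence], Partition]


def _default_base(cfg: RGConfig) -> BasePartitioner:
    def base(g: Graph, seed_seq: np.random.SeedSequence) -> Partition:
        return randomized_greedy(g, cfg, seed_seq=seed_seq)

    return base


def run_reneel(
    g: Graph,
    k_max: int = 100,
    k_prime: int = 20,
    base: BasePartitioner | None = None,
    reduced_base: BasePartitioner | None = None,
    seed: int | np.random.SeedSequence | None = None,
    rg_config: RGConfig | None = None,
    on_iteration: Callable[[int, CoreGrouping, Ensemble], None] | None = None,
) -> tuple[Partition, RunTrace]:
    """Run the full consensus scheme and return (consensus partition, trace).

    Parameters
    ----------
    g : Graph
        Input graph (m > 0).
    k_max, k_prime : int
        Ensemble capacity and number of reduced-network partitions drawn
        per iteration.  Defaults 100 and 20.
    base, reduced_base : callable, optional
        Base partitioners ``(graph, seed_sequence) -> Partition`` for the
        original and reduced networks.  Default: randomized greedy with
        ``rg_config`` for both (the reduced-network base may differ).
    seed : int or SeedSequence, optional
        Root of all randomness; runs are deterministic given it.
    on_iteration : callable, optional
        Hook called after each extremal update with
        ``(iteration, core_grouping, ensemble)``; used for diagnostics.

    With ``k_max=1`` the single base partition is already the consensus and
    the loop body never runs.
    """
    if k_max < 1 or k_prime < 1:
        raise ValueError("k_max and k_prime must be >= 1")
    g.require_weight()
    cfg = rg_config or RGConfig()
    base = base or _default_base(cfg)
    reduced_base = reduced_base or _default_base(cfg)
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    init_seed, loop_seed = root.spawn(2)

    # initial ensemble: k_max base runs, deduplicated under canonical form
    seen: set[tuple[int, ...]] = set()
    members: list[Partition] = []
    for child in init_seed.spawn(k_max):
        p = base(g, child)
        if p.q is None:
            p.q = modularity(g, p)
        if p.canonical() not in seen:
            seen.add(p.canonical())
            members.append(p)
    ens = Ensemble(members, k_max=k_max)

    trace = RunTrace()
    iteration = 0
    while ens.k > 1:
        iteration += 1
        cg = core_groups(ens.members)
        reduced = reduce_graph(g, cg)
        (iter_seed,) = loop_seed.spawn(1)
        best_rp: Partition | None = None
        for child in iter_seed.spawn(k_prime):
            rp = reduced_base(reduced.graph, child)
            if rp.q is None:
                rp.q = modularity(reduced.graph, rp)
            if best_rp is None or rp.q > best_rp.q:  # ties: first generated
                best_rp = rp
        assert best_rp is not None
        candidate = expand_partition(best_rp, reduced)
        candidate.q = modularity(g, candidate)
        if abs(candidate.q - best_rp.q) > _PRESERVATION_ATOL:
            raise RuntimeError(
                "modularity not preserved under reduction/expansion: "
                f"{best_rp.q!r} vs {candidate.q!r}")
        trace_q_candidate = candidate.q
        ens.extremal_update(candidate)
        trace.append(iteration, ens.best.q, ens.worst.q, trace_q_candidate,
                     cg.count, ens.k)
        if on_iteration is not None:
            on_iteration(iteration, cg, ens)

    return ens.best, trace
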