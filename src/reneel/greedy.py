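"""Stochastic base partitioners.

The workhorse is randomized greedy (RG) agglomeration: start from singleton
communities and repeatedly merge the pair with the largest modularity gain
among a small random sample of communities and their neighbors, all the way
down to a single community; return the partition at the dendrogram level
where Q peaked.  Sampling (default: 2 communities per step) is what makes
the algorithm stochastic and cheap — expected cost O(m log n) — while the
best-level bookkeeping guarantees the returned Q is at least 0 on loop-free
graphs (the final one-community level always has Q = 0).

``naive_best`` is the conventional comparator: run RG k times, keep the
best.  ``make_ensemble`` produces the deduplicated ensembles the consensus
scheme consumes.  All functions are deterministic given their seed; per-run
seeds are spawned from a single :class:`numpy.random.SeedSequence` so a
shared root seed yields paired ensembles across schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import Graph
from .quality import Partition, canonical_form, modularity

__all__ = ["RGConfig", "randomized_greedy", "make_ensemble", "naive_best"]


@dataclass
class RGConfig:
    """Randomized-greedy configuration.

    sample_size : communities drawn per merge step (>= 1; default 2, the
        classic randomized-greedy choice).
    rng_seed : root seed; ``None`` draws fresh OS entropy.
    """
    sample_size: int = 2
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")


def _seed_seq(cfg: RGConfig | None,
              seed_seq: np.random.SeedSequence | None) -> np.random.SeedSequence:
    if seed_seq is not None:
        return seed_seq
    seed = cfg.rng_seed if cfg is not None else None
    return np.random.SeedSequence(seed)


def _sample_indices(uniforms, r: int, k: int) -> list[int]:
    """k distinct indices from range(r) via Floyd's algorithm, consuming k
    uniforms from the supplied iterator (cheap for the tiny k per step)."""
    if k >= r:
        return list(range(r))
    chosen: set[int] = set()
    out: list[int] = []
    for t in range(r - k, r):
        i = int(next(uniforms) * (t + 1))
        if i in chosen:
            i = t
        chosen.add(i)
        out.append(i)
    return out


def _rg_engine(g: Graph, sample_size: int, rng: np.random.Generator) -> np.ndarray:
    """One RG run; returns the best-level label array (not canonicalized)."""
    n = g.n
    m = g.require_weight()
    inv2m = 1.0 / (2.0 * m)
    inv2m_sq = inv2m * inv2m

    # community-level state; community ids start as node ids
    nbr: list[dict[int, float]] = [dict() for _ in range(n)]
    m_int = [0.0] * n
    for u, nbrs in enumerate(g._adj):
        for v, w in nbrs.items():
            if v == u:
                m_int[u] = w
            else:
                nbr[u][v] = w
    s: list[float] = g.strength.tolist()
    comm_of = np.arange(n, dtype=np.int64)
    members: list[list[int]] = [[v] for v in range(n)]

    alive = list(range(n))
    alive_pos = list(range(n))  # alive_pos[c] = index of c in alive

    q = sum(m_int) / m - sum(x * x for x in s) * inv2m_sq
    best_q = q
    best_labels = comm_of.copy()

    # one batched draw of uniforms covers every merge step's sampling
    uniforms = iter(rng.random(sample_size * max(n - 1, 1)))

    neg_inf = float("-inf")
    for _ in range(n - 1):
        r = len(alive)
        sample = [alive[i] for i in _sample_indices(uniforms, r, min(sample_size, r))]

        best_d = neg_inf
        b_lo = b_hi = -1
        for a in sample:
            sa_sq = s[a] * inv2m_sq
            for b, w in nbr[a].items():
                d = 2.0 * (w * inv2m - sa_sq * s[b])
                if d > best_d:
                    best_d = d
                    b_lo, b_hi = (a, b) if a < b else (b, a)
                elif d == best_d:
                    pair = (a, b) if a < b else (b, a)
                    if pair < (b_lo, b_hi):
                        b_lo, b_hi = pair
        if b_lo < 0:
            # every sampled community is isolated from the rest: merge the
            # lowest-id sampled community with the lowest other alive one
            a = min(sample)
            b = min(c for c in alive if c != a)
            b_lo, b_hi = (a, b) if a < b else (b, a)
            best_d = -2.0 * s[a] * s[b] * inv2m_sq

        lo, hi = b_lo, b_hi
        # merge hi into lo
        w_ab = nbr[lo].pop(hi, 0.0)
        nbr[hi].pop(lo, None)
        m_int[lo] += m_int[hi] + w_ab
        s[lo] += s[hi]
        for c, w in nbr[hi].items():
            del nbr[c][hi]
            nw = nbr[lo].get(c, 0.0) + w
            nbr[lo][c] = nw
            nbr[c][lo] = nw
        nbr[hi].clear()
        mh = members[hi]
        if len(mh) == 1:
            comm_of[mh[0]] = lo
        else:
            comm_of[mh] = lo
        members[lo].extend(mh)
        members[hi] = []
        # remove hi from alive (swap-pop)
        p = alive_pos[hi]
        last = alive[-1]
        alive[p] = last
        alive_pos[last] = p
        alive.pop()

        q += best_d
        if q > best_q:  # ties keep the earliest level
            best_q = q
            best_labels = comm_of.copy()

    return best_labels


def randomized_greedy(g: Graph, cfg: RGConfig | None = None, *,
                      seed_seq: np.random.SeedSequence | None = None) -> Partition:
    """One randomized-greedy run; deterministic given the seed.

    Returns the partition at the merge level with maximal recorded Q (the
    all-singletons start counts as a level), with its modularity recomputed
    from scratch and cached on ``.q``.
    """
    cfg = cfg or RGConfig()
    rng = np.random.default_rng(_seed_seq(cfg, seed_seq))
    labels = _rg_engine(g, cfg.sample_size, rng)
    p = Partition(np.asarray(canonical_form(labels), dtype=np.int64))
    p.q = modularity(g, p)
    return p


def make_ensemble(g: Graph, k: int, cfg: RGConfig | None = None, *,
                  seed_seq: np.random.SeedSequence | None = None) -> list[Partition]:
    """k independent RG runs with spawned per-run seeds, deduplicated under
    canonical form (result holds <= k distinct partitions, generation order
    preserved)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    cfg = cfg or RGConfig()
    root = _seed_seq(cfg, seed_seq)
    seen: set[tuple[int, ...]] = set()
    out: list[Partition] = []
    for child in root.spawn(k):
        p = randomized_greedy(g, cfg, seed_seq=child)
        key = p.canonical()
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def naive_best(g: Graph, k: int, cfg: RGConfig | None = None, *,
               seed_seq: np.random.SeedSequence | None = None) -> Partition:
    """Best-of-k comparator: run RG k times, keep the largest-Q partition
    (ties: first generated).  Uses the same seed spawning as
    :func:`make_ensemble`, so the two are paired under a shared seed."""
    if k < 1:
        raise ValueError("k must be >= 1")
    cfg = cfg or RGConfig()
    root = _seed_seq(cfg, seed_seq)
    best: Partition | None = None
    for child in root.spawn(k):
        p = randomized_greedy(g, cfg, seed_seq=child)
        if best is None or p.q > best.q:
            best = p
    assert best is not None
    return best
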