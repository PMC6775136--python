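"""Co-clustering diagnostics and simulated-annealing seriation.

The co-clustering matrix of an ensemble has entries s_ij equal to the
fraction of partitions placing nodes i and j in the same community
(s_ii = 1; pairs inside one core group have s_ij = 1 by definition).  To
visualize its block structure the nodes are reordered to minimize

    H = sum_{i<j} s_ij * d_ij^alpha

where d_ij is the circular distance between the two nodes' positions in
the order (minimum distance from the diagonal under periodic boundary
conditions) and alpha (default 3) sharpens the penalty on distant bright
pixels.  Minimization uses Metropolis simulated annealing over random pair
swaps with Boltzmann factor exp(-dH/T) and geometric cooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .quality import Partition

__all__ = [
    "co_cluster_matrix",
    "seriation_cost",
    "anneal_order",
    "SeriationConfig",
]


def co_cluster_matrix(partitions: Sequence[Partition | np.ndarray]) -> np.ndarray:
    """s_ij = fraction of partitions with node i and node j co-membered."""
    if len(partitions) == 0:
        raise ValueError("need at least one partition")
    n = None
    acc = None
    for p in partitions:
        lab = p.labels if isinstance(p, Partition) else np.asarray(p)
        if n is None:
            n = len(lab)
            acc = np.zeros((n, n))
        elif len(lab) != n:
            raise ValueError("partitions cover different node sets")
        acc += lab[:, None] == lab[None, :]
    s = acc / len(partitions)
    return s


def _circular_distance_powers(n: int, alpha: float) -> np.ndarray:
    """Matrix D[p, q] = min(|p-q|, n-|p-q|)^alpha over positions."""
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    d = np.minimum(d, n - d)
    return d.astype(float) ** alpha


def seriation_cost(s: np.ndarray, order: np.ndarray, alpha: float = 3.0) -> float:
    """H = sum_{i<j} s_ij d_ij^alpha for the given node order.

    ``order[p]`` is the node placed at position p; d_ij is the circular
    distance between the positions of i and j.
    """
    s = np.asarray(s)
    n = s.shape[0]
    order = np.asarray(order)
    if sorted(order.tolist()) != list(range(n)):
        raise ValueError("order is not a permutation of 0..n-1")
    dp = _circular_distance_powers(n, alpha)
    sr = s[np.ix_(order, order)]
    iu = np.triu_indices(n, k=1)
    return float((sr[iu] * dp[iu]).sum())


@dataclass
class SeriationConfig:
    """Annealing controls.

    alpha : exponent on the circular distance (default 3).
    t_start : initial temperature; ``None`` uses a heuristic (std of dH
        over 100 random swaps, times 10), high enough that the starting
        order is effectively randomized.
    cooling : geometric cooling factor per stage (0 < cooling < 1).
    steps_per_stage : proposed swaps per temperature stage (default n^2).
    stall_stages : stop after this many consecutive stages with no
        accepted move.
    rng_seed : seed; annealing is deterministic given it.
    """
    alpha: float = 3.0
    t_start: float | None = None
    cooling: float = 0.98
    steps_per_stage: int | None = None
    stall_stages: int = 3
    max_stages: int = 5000
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling factor must be in (0, 1)")


def _swap_delta(s: np.ndarray, dp: np.ndarray, pos: np.ndarray,
                u: int, v: int) -> float:
    """dH for swapping the positions of nodes u and v.

    Only pairs involving u or v change, and the (u, v) pair itself does not
    (the circular distance is symmetric in the swap):

        dH = sum_{w not in {u,v}} (s_uw - s_vw) (D[p_v, p_w] - D[p_u, p_w])
    """
    pu, pv = pos[u], pos[v]
    diff = dp[pv, pos] - dp[pu, pos]
    sdiff = s[u] - s[v]
    delta = float(sdiff @ diff)
    delta -= float(sdiff[u] * diff[u] + sdiff[v] * diff[v])
    return delta


def anneal_order(s: np.ndarray, cfg: SeriationConfig | None = None) -> np.ndarray:
    """Simulated-annealing seriation; returns the best-seen order.

    Starts from the identity order (the initial high temperature randomizes
    it); never returns an order with H above the starting order's H.
    """
    cfg = cfg or SeriationConfig()
    s = np.asarray(s, dtype=float)
    n = s.shape[0]
    if n < 2:
        return np.arange(n)
    rng = np.random.default_rng(cfg.rng_seed)
    dp = _circular_distance_powers(n, cfg.alpha)

    order = np.arange(n)
    pos = np.arange(n)
    iu = np.triu_indices(n, k=1)
    h = float((s[np.ix_(order, order)][iu] * dp[iu]).sum())
    best_h = h
    best_order = order.copy()

    if cfg.t_start is None:
        # heuristic: spread of dH over random swaps, scaled up
        deltas = []
        for _ in range(100):
            u, v = rng.choice(n, size=2, replace=False)
            deltas.append(_swap_delta(s, dp, pos, int(u), int(v)))
        t = 10.0 * (float(np.std(deltas)) or 1.0)
    else:
        t = float(cfg.t_start)

    steps = cfg.steps_per_stage if cfg.steps_per_stage is not None else n * n
    stale = 0
    for _ in range(cfg.max_stages):
        accepted = 0
        for _ in range(steps):
            u, v = rng.choice(n, size=2, replace=False)
            u, v = int(u), int(v)
            delta = _swap_delta(s, dp, pos, u, v)
            if delta <= 0.0 or rng.random() < np.exp(-delta / t):
                pu, pv = pos[u], pos[v]
                order[pu], order[pv] = v, u
                pos[u], pos[v] = pv, pu
                h += delta
                if abs(delta) > 1e-12:  # zero-cost plateau moves don't reset stalling
                    accepted += 1
                if h < best_h - 1e-12:
                    best_h = h
                    best_order = order.copy()
        stale = stale + 1 if accepted == 0 else 0
        if stale >= cfg.stall_stages:
            break
        t *= cfg.cooling

    return best_order
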