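import numpy as np
import pytest

from reneel.generators import PlantedSpec, planted_partition, ring_of_cliques
from reneel.graph import Graph
from reneel.greedy import RGConfig, make_ensemble
from reneel.quality import Partition, modularity
from reneel.scheme import (Ensemble, core_groups, expand_partition, reduce_graph,
                           run_reneel)

from conftest import random_graph, random_labels


def pairwise_meet_oracle(label_rows: list[np.ndarray]) -> np.ndarray:
    """O(n^2 k) brute-force co-membership matrix: nodes grouped iff
    co-membered in every partition."""
    co = None
    for lab in label_rows:
        eq = lab[:, None] == lab[None, :]
        co = eq if co is None else (co & eq)
    return co


class TestCoreGroups:
    def test_meet_of_one_partition_is_that_partition(self):
        labels = np.array([0, 0, 1, 1, 2])
        cg = core_groups([labels])
        assert (cg.group_of == np.array([0, 0, 1, 1, 2])).all()

    def test_crossing_partitions_give_singletons(self):
        cg = core_groups([np.array([0, 0, 1]), np.array([0, 1, 1])])
        assert cg.count == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = [random_labels(rng, 50, int(rng.integers(2, 8))) for _ in range(20)]
        cg = core_groups(rows)
        ours = cg.group_of[:, None] == cg.group_of[None, :]
        assert (ours == pairwise_meet_oracle(rows)).all()
        # maximality: every pair of distinct groups is separated somewhere
        assert cg.count == len({tuple(r[i] for r in rows) for i in range(50)})

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(ValueError, match="different node sets"):
            core_groups([np.array([0, 1]), np.array([0, 1, 2])])


class TestReduceExpand:
    def test_identity_reduction(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng, 10, 0.4)
        cg = core_groups([np.arange(g.n)])
        rg = reduce_graph(g, cg)
        assert rg.graph.n == g.n and rg.graph.m == g.m
        assert sorted(rg.graph.edges()) == sorted(g.edges())

    def test_collapsed_triangle_becomes_self_loop(self, triangle):
        cg = core_groups([np.zeros(3, dtype=int)])
        rg = reduce_graph(triangle, cg)
        assert rg.graph.n == 1
        assert rg.graph.neighbors(0) == {0: 3.0}
        assert rg.graph.m == 3.0

    def test_seven_group_reduction(self):
        """A grouping with five multi-node groups and two singletons yields
        a seven-node reduced network preserving total weight."""
        rng = np.random.default_rng(1)
        g = random_graph(rng, 22, 0.3, connected=True)
        sizes = [4, 4, 4, 4, 4, 1, 1]
        group_of = np.repeat(np.arange(7), sizes)
        cg = core_groups([group_of])
        rg = reduce_graph(g, cg)
        assert rg.graph.n == 7
        assert rg.graph.m == pytest.approx(g.m, abs=1e-12)
        # self-loop of each group equals its internal weight in g
        u, v, w = g.edge_arrays()
        for gid in range(7):
            internal = w[(group_of[u] == gid) & (group_of[v] == gid)].sum()
            assert rg.graph.neighbors(gid).get(gid, 0.0) == pytest.approx(internal)

    def test_expand_identity_and_single_community(self, two_triangles):
        cg = core_groups([np.arange(6)])
        rg = reduce_graph(two_triangles, cg)
        p = expand_partition(np.array([0, 0, 0, 1, 1, 1]), rg)
        assert (p.labels == np.array([0, 0, 0, 1, 1, 1])).all()
        allone = expand_partition(np.zeros(6, dtype=int), rg)
        assert modularity(two_triangles, allone) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_modularity_preserved_under_reduction(self, seed):
        """Q on the reduced graph equals Q of the expanded partition on the
        original graph to 1e-12; this identity is what makes the scheme
        valid."""
        rng = np.random.default_rng(seed)
        g = random_graph(rng, int(rng.integers(8, 30)), 0.3,
                         weighted=bool(seed % 2))
        rows = [random_labels(rng, g.n, int(rng.integers(2, 6))) for _ in range(4)]
        cg = core_groups(rows)
        rg = reduce_graph(g, cg)
        rlabels = random_labels(rng, rg.graph.n, 4)
        q_reduced = modularity(rg.graph, rlabels)
        q_expanded = modularity(g, expand_partition(rlabels, rg))
        assert q_expanded == pytest.approx(q_reduced, abs=1e-12)


def _member(labels, g):
    p = Partition(np.asarray(labels))
    p.q = modularity(g, p)
    return p


class TestExtremalUpdate:
    def make_ensemble(self, g):
        members = [
            _member([0, 0, 0, 1, 1, 1], g),   # Q = 0.5
            _member([0, 0, 1, 1, 2, 2], g),
            _member([0, 1, 2, 3, 4, 5], g),   # Q < 0
        ]
        return Ensemble(members, k_max=3)

    def test_replacement_at_capacity_raises_min_q(self, two_triangles):
        ens = self.make_ensemble(two_triangles)
        old_min = ens.worst.q
        candidate = _member([0, 0, 0, 1, 2, 2], two_triangles)
        assert candidate.q > old_min
        tag = ens.extremal_update(candidate)
        assert tag == "accepted"
        assert ens.k == 3
        assert ens.worst.q > old_min

    def test_duplicate_shrinks_regardless_of_q(self, two_triangles):
        ens = self.make_ensemble(two_triangles)
        dup = _member([5, 5, 5, 9, 9, 9], two_triangles)  # == best under canon
        tag = ens.extremal_update(dup)
        assert tag == "duplicate"
        assert ens.k == 2

    def test_growth_below_capacity(self, two_triangles):
        members = [_member([0, 0, 1, 1, 2, 2], two_triangles)]
        ens = Ensemble(members, k_max=3)
        tag = ens.extremal_update(_member([0, 0, 0, 1, 1, 1], two_triangles))
        assert tag == "accepted" and ens.k == 2
        assert ens.best.q == pytest.approx(0.5)

    def test_rejection_shrinks(self, two_triangles):
        ens = self.make_ensemble(two_triangles)
        bad = _member([0, 1, 2, 3, 4, 0], two_triangles)
        assert bad.q <= ens.worst.q
        tag = ens.extremal_update(bad)
        assert tag == "rejected" and ens.k == 2

    def test_ordering_invariant(self, two_triangles):
        ens = self.make_ensemble(two_triangles)
        qs = [p.q for p in ens.members]
        assert qs == sorted(qs, reverse=True)


class TestRunReneel:
    def test_k_max_one_returns_base_partition_immediately(self, two_triangles):
        best, trace = run_reneel(two_triangles, k_max=1, k_prime=5, seed=0)
        assert len(trace) == 0
        single = make_ensemble(two_triangles, 1, RGConfig(),
                               seed_seq=np.random.SeedSequence(0).spawn(2)[0])[0]
        assert best == single

    def test_two_triangles_consensus(self, two_triangles):
        best, _ = run_reneel(two_triangles, k_max=10, k_prime=5, seed=1)
        assert best.q == pytest.approx(0.5, abs=1e-12)

    def test_ring_consensus_at_least_clique_partition(self):
        g, cliques = ring_of_cliques(8, 5)
        q_cliques = modularity(g, cliques)
        best, _ = run_reneel(g, k_max=20, k_prime=5, seed=3)
        assert best.q >= q_cliques - 1e-12

    def test_deterministic_given_seed(self):
        g, _ = planted_partition(PlantedSpec(3, 10, 0.4, 0.05, rng_seed=4))
        b1, t1 = run_reneel(g, k_max=15, k_prime=4, seed=42)
        b2, t2 = run_reneel(g, k_max=15, k_prime=4, seed=42)
        assert (b1.labels == b2.labels).all() and b1.q == b2.q
        assert t1.q_best == t2.q_best and t1.n_reduced == t2.n_reduced

    def test_trace_and_monotonicity_invariants(self):
        """Across a full run: reduced size non-increasing, min-Q and max-Q
        non-decreasing, core groups only coarsen, and the loop terminates
        with the consensus at least as good as every initial partition."""
        g, _ = planted_partition(PlantedSpec(4, 10, 0.3, 0.05, rng_seed=5))
        groupings = []

        def on_iter(it, cg, ens):
            groupings.append(cg.group_of.copy())

        init = make_ensemble(g, 15, RGConfig(),
                             seed_seq=np.random.SeedSequence(7).spawn(2)[0])
        best, trace = run_reneel(g, k_max=15, k_prime=4, seed=7, on_iteration=on_iter)
        assert len(trace) >= 1  # terminated
        nr = trace.n_reduced
        assert all(a >= b for a, b in zip(nr, nr[1:]))
        assert all(a <= b + 1e-15 for a, b in zip(trace.q_worst, trace.q_worst[1:]))
        assert all(a <= b + 1e-15 for a, b in zip(trace.q_best, trace.q_best[1:]))
        assert all(1 <= k <= 15 for k in trace.k)
        # agglomerative coarsening: same earlier group -> same later group
        for g0, g1 in zip(groupings, groupings[1:]):
            mapped = {}
            for a, b in zip(g0, g1):
                assert mapped.setdefault(a, b) == b
        # consensus beats every initial ensemble member
        assert all(best.q >= p.q - 1e-15 for p in init)

    def test_trace_frame_columns(self, two_triangles):
        g, _ = planted_partition(PlantedSpec(3, 8, 0.4, 0.05, rng_seed=6))
        _, trace = run_reneel(g, k_max=8, k_prime=3, seed=0)
        df = trace.to_frame()
        assert list(df.columns) == ["iteration", "q_best", "q_worst",
                                    "q_candidate", "n_reduced", "k"]
        assert len(df) == len(trace)

    def test_invalid_parameters(self, two_triangles):
        with pytest.raises(ValueError):
            run_reneel(two_triangles, k_max=0)
        with pytest.raises(ValueError):
            run_reneel(two_triangles, k_prime=0)
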