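import numpy as np
import pytest

from reneel.graph import (Graph, GraphFormatError, read_edge_list, read_membership,
                          read_metis, write_edge_list, write_membership, write_metis)
from reneel.quality import Partition, canonical_form

from conftest import random_graph


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestEdgeList:
    def test_triangle(self, tmp_path):
        g = read_edge_list(write(tmp_path, "t.edges", "0 1\n1 2\n0 2\n"))
        assert g.n == 3 and g.m == 3
        assert np.allclose(g.strength, 2.0)

    def test_reversed_duplicate_unweighted_collapses_to_one(self, tmp_path):
        g = read_edge_list(write(tmp_path, "d.edges", "a b\nb a\n"))
        assert g.n == 2 and g.m == 1.0

    def test_reversed_duplicate_weighted_sums(self, tmp_path):
        g = read_edge_list(write(tmp_path, "d.edges", "a b 1\nb a 1\n"), weighted=True)
        assert g.m == 2.0

    def test_comments_and_labels_preserved(self, tmp_path):
        g = read_edge_list(write(tmp_path, "c.edges", "# header\nx y\ny z\n"))
        assert g.labels == ["x", "y", "z"]
        assert g.n == 3 and g.m == 2

    def test_self_loop_rejected_by_default(self, tmp_path):
        p = write(tmp_path, "s.edges", "a a\n")
        with pytest.raises(GraphFormatError, match="self-loop"):
            read_edge_list(p)
        g = read_edge_list(p, allow_self_loops=True)
        assert g.m == 1.0 and g.strength[0] == 2.0

    def test_malformed_line_names_line_number(self, tmp_path):
        with pytest.raises(GraphFormatError, match=":2:"):
            read_edge_list(write(tmp_path, "m.edges", "a b\na b c d\n"))

    def test_nonpositive_weight_rejected(self, tmp_path):
        with pytest.raises(GraphFormatError, match="non-positive"):
            read_edge_list(write(tmp_path, "w.edges", "a b -1\n"), weighted=True)

    def test_round_trip_identity_on_merged_edges(self, tmp_path):
        rng = np.random.default_rng(0)
        g = random_graph(rng, 12, 0.4, weighted=True)
        path = tmp_path / "rt.edges"
        write_edge_list(g, path, weighted=True)
        g2 = read_edge_list(path, weighted=True)
        # compare by original labels: ids may be renumbered on re-read
        e1 = {tuple(sorted((str(g.labels[u]), str(g.labels[v])))): w
              for u, v, w in g.edges()}
        e2 = {tuple(sorted((g2.labels[u], g2.labels[v]))): w
              for u, v, w in g2.edges()}
        assert e1.keys() == e2.keys()
        for k in e1:
            assert e2[k] == pytest.approx(e1[k], rel=1e-5)


class TestMetis:
    def test_triangle(self, tmp_path):
        g = read_metis(write(tmp_path, "t.graph", "3 3\n2 3\n1 3\n1 2\n"))
        assert g.n == 3 and g.m == 3

    def test_edge_count_mismatch_is_error(self, tmp_path):
        text = "3 3\n2 3\n1 3\n1 2\n"  # header lies: declare m=2
        with pytest.raises(GraphFormatError, match="declares m"):
            read_metis(write(tmp_path, "bad.graph", text.replace("3 3", "3 2", 1)))

    def test_header_node_count_mismatch(self, tmp_path):
        with pytest.raises(GraphFormatError, match="adjacency lines"):
            read_metis(write(tmp_path, "bad.graph", "4 3\n2 3\n1 3\n1 2\n"))

    def test_weighted_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        g = random_graph(rng, 10, 0.4, weighted=True)
        path = tmp_path / "w.graph"
        write_metis(g, path, weighted=True)
        g2 = read_metis(path)
        assert g2.n == g.n
        # weights survive the %g text round trip
        e1 = {(u, v): w for u, v, w in g.edges()}
        e2 = {(u, v): w for u, v, w in g2.edges()}
        assert e1.keys() == e2.keys()
        for k in e1:
            assert e2[k] == pytest.approx(e1[k], rel=1e-5)

    def test_self_loops_not_representable(self, tmp_path):
        g = Graph.from_edges(2, [(0, 0, 1.0), (0, 1, 1.0)])
        with pytest.raises(ValueError, match="self-loop"):
            write_metis(g, tmp_path / "s.graph")


class TestMembership:
    def test_single_community_triangle(self, tmp_path, triangle):
        path = tmp_path / "m.tsv"
        write_membership(np.array([7, 7, 7]), triangle.labels, path)
        lines = path.read_text().splitlines()
        assert [ln.split("\t")[1] for ln in lines] == ["0", "0", "0"]

    def test_two_triangle_split_ids(self, tmp_path, two_triangles):
        path = tmp_path / "m.tsv"
        write_membership(np.array([3, 3, 3, 9, 9, 9]), two_triangles.labels, path)
        comms = {ln.split("\t")[1] for ln in path.read_text().splitlines()}
        assert comms == {"0", "1"}

    def test_round_trip_canonical_equality(self, tmp_path):
        rng = np.random.default_rng(2)
        g = random_graph(rng, 15, 0.3)
        labels = rng.integers(0, 4, size=g.n)
        path = tmp_path / "m.tsv"
        write_membership(labels, g.labels, path)
        back = read_membership(path, g.labels)
        assert Partition(labels) == Partition(back)

    def test_missing_node_is_error(self, tmp_path, triangle):
        path = tmp_path / "m.tsv"
        path.write_text("0\t0\n1\t0\n")
        with pytest.raises(GraphFormatError, match="without membership"):
            read_membership(path, triangle.labels)


@pytest.mark.parametrize("seed", range(5))
def test_strength_sum_is_twice_total_weight(seed):
    rng = np.random.default_rng(seed)
    g = random_graph(rng, int(rng.integers(5, 25)), 0.3, weighted=bool(seed % 2))
    assert g.strength.sum() == pytest.approx(2 * g.m, abs=1e-12)
    assert set(range(g.n)) == set(range(len(g.labels)))


def test_parallel_input_edges_merge_by_summation():
    g = Graph.from_edges(3, [(0, 1, 1.0), (1, 0, 2.0), (1, 2, 1.0)])
    assert g.num_edges == 2 and g.m == 4.0


def test_canonical_form_in_label_space():
    assert canonical_form([5, 5, 2]) == (0, 0, 1)
    assert canonical_form([0, 1, 0]) == canonical_form([7, 3, 7])
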