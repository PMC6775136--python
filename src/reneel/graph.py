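"""Undirected weighted graph container and readers/writers.

The graph model is deliberately small: dense 0-based integer node ids, an
adjacency map with strictly positive edge weights, and self-loops stored
once.  The self-loop convention is fixed globally and matters: a self-loop
of weight ``w`` contributes ``w`` to the total weight ``m``, ``w`` to the
internal weight of its node's community, and ``2w`` to its node's strength.
This is the unique convention under which collapsing groups of nodes into
single weighted nodes preserves modularity exactly, which is what makes the
reduced-network consensus scheme valid.

Supported formats are plain edge lists (whitespace separated, optional
weight column, ``#`` comments), METIS ``.graph`` files, and a two-column
membership TSV for partitions.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "GraphFormatError",
    "read_edge_list",
    "read_metis",
    "write_metis",
    "write_edge_list",
    "write_membership",
    "read_membership",
]


class GraphFormatError(ValueError):
    """Raised for malformed or inconsistent graph input."""


class Graph:
    """Undirected weighted graph with self-loops.

    Parameters
    ----------
    n : int
        Number of nodes; ids are ``0 .. n-1``.
    adj : list of dict, optional
        Adjacency maps ``adj[u][v] = weight``; symmetric, self-loops stored
        at ``adj[v][v]`` once.  Use :meth:`from_edges` rather than building
        this by hand.
    labels : sequence, optional
        Original node labels, index-aligned with internal ids.
    """

    __slots__ = ("n", "_adj", "labels", "_m", "_strength", "_edge_arrays")

    def __init__(self, n: int, adj: list[dict[int, float]] | None = None,
                 labels: Sequence | None = None):
        if n <= 0:
            raise ValueError("graph must have at least one node")
        self.n = int(n)
        self._adj: list[dict[int, float]] = adj if adj is not None else [dict() for _ in range(n)]
        if len(self._adj) != self.n:
            raise ValueError("adjacency length does not match n")
        self.labels = list(labels) if labels is not None else list(range(n))
        if len(self.labels) != self.n:
            raise ValueError("labels length does not match n")
        self._m: float | None = None
        self._strength: np.ndarray | None = None
        self._edge_arrays: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    # -- construction ---------------------------------------------------

    @classmethod
    def from_edges(cls, n: int, edges: Iterable[tuple[int, int, float]],
                   labels: Sequence | None = None) -> "Graph":
        """Build a graph from ``(u, v, w)`` triples, merging duplicates by
        summing weights.  Self-pairs become self-loops."""
        g = cls(n, labels=labels)
        adj = g._adj
        for u, v, w in edges:
            w = float(w)
            if w <= 0:
                raise ValueError(f"edge ({u}, {v}) has non-positive weight {w}")
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u}, {v}) outside node range 0..{n - 1}")
            adj[u][v] = adj[u].get(v, 0.0) + w
            if u != v:
                adj[v][u] = adj[v].get(u, 0.0) + w
        return g

    # -- cached aggregates ----------------------------------------------

    def edges(self) -> Iterator[tuple[int, int, float]]:
        """Yield each undirected edge once as ``(u, v, w)`` with u <= v."""
        for u, nbrs in enumerate(self._adj):
            for v, w in nbrs.items():
                if v >= u:
                    yield u, v, w

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Edges as parallel arrays ``(u, v, w)``; cached."""
        if self._edge_arrays is None:
            us, vs, ws = [], [], []
            for u, v, w in self.edges():
                us.append(u)
                vs.append(v)
                ws.append(w)
            self._edge_arrays = (
                np.asarray(us, dtype=np.int64),
                np.asarray(vs, dtype=np.int64),
                np.asarray(ws, dtype=np.float64),
            )
        return self._edge_arrays

    @property
    def m(self) -> float:
        """Total weight: sum of edge weights, each self-loop counted once."""
        if self._m is None:
            self._m = float(self.edge_arrays()[2].sum())
        return self._m

    @property
    def strength(self) -> np.ndarray:
        """Node strengths; a self-loop of weight w contributes 2w."""
        if self._strength is None:
            u, v, w = self.edge_arrays()
            s = np.zeros(self.n)
            np.add.at(s, u, w)
            np.add.at(s, v, w)
            self._strength = s
        return self._strength

    @property
    def num_edges(self) -> int:
        return len(self.edge_arrays()[2])

    def neighbors(self, v: int) -> dict[int, float]:
        return self._adj[v]

    def has_self_loops(self) -> bool:
        return any(v in nbrs for v, nbrs in enumerate(self._adj))

    def require_weight(self) -> float:
        if self.m <= 0:
            raise ValueError("graph has no edges; modularity is undefined (m = 0)")
        return self.m

    def __repr__(self) -> str:  # pragma: no cover
        return f"Graph(n={self.n}, edges={self.num_edges}, m={self.m:g})"


# ---------------------------------------------------------------------------
# edge list format
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, weighted: bool = False,
                   allow_self_loops: bool = False) -> Graph:
    """Read a whitespace-separated edge list.

    Lines starting with ``#`` (or ``%``) are comments.  Node labels may be
    arbitrary strings and are remapped to dense 0-based ids in order of first
    appearance; the label map is kept on the returned graph.

    Duplicate undirected edges (including reversed pairs) are collapsed to
    weight 1 in unweighted input (repeated lines are redundancy and logged);
    in weighted input duplicate weights sum.

    Self-loops are rejected by default — the benchmark corpora this reader
    targets have none — unless ``allow_self_loops`` is set.
    """
    path = Path(path)
    label_to_id: dict[str, int] = {}
    edges: dict[tuple[int, int], float] = {}
    duplicates = 0

    def node_id(tok: str) -> int:
        i = label_to_id.get(tok)
        if i is None:
            i = len(label_to_id)
            label_to_id[tok] = i
        return i

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("%"):
                continue
            toks = line.split()
            want = 3 if weighted else 2
            if len(toks) != want:
                # tolerate a weight column in unweighted mode only if absent
                raise GraphFormatError(
                    f"{path}:{lineno}: expected {want} tokens, got {len(toks)}")
            u, v = node_id(toks[0]), node_id(toks[1])
            if u == v and not allow_self_loops:
                raise GraphFormatError(
                    f"{path}:{lineno}: self-loop on node {toks[0]!r} "
                    "(pass allow_self_loops=True to accept)")
            if weighted:
                try:
                    w = float(toks[2])
                except ValueError as exc:
                    raise GraphFormatError(f"{path}:{lineno}: bad weight {toks[2]!r}") from exc
                if w <= 0:
                    raise GraphFormatError(f"{path}:{lineno}: non-positive weight {w}")
            else:
                w = 1.0
            key = (u, v) if u <= v else (v, u)
            if key in edges:
                duplicates += 1
                if weighted:
                    edges[key] += w
                # unweighted duplicates collapse to weight 1
            else:
                edges[key] = w

    if not label_to_id:
        raise GraphFormatError(f"{path}: no edges found")
    if duplicates:
        logger.info("%s: merged %d duplicate edge line(s)", path, duplicates)
    labels = [None] * len(label_to_id)
    for lab, i in label_to_id.items():
        labels[i] = lab
    return Graph.from_edges(len(labels), ((u, v, w) for (u, v), w in edges.items()),
                            labels=labels)


def write_edge_list(g: Graph, path: str | Path, weighted: bool = False) -> None:
    """Write the graph as an edge list using original labels."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v, w in g.edges():
            if weighted:
                fh.write(f"{g.labels[u]}\t{g.labels[v]}\t{w:g}\n")
            else:
                fh.write(f"{g.labels[u]}\t{g.labels[v]}\n")


# ---------------------------------------------------------------------------
# METIS format
# ---------------------------------------------------------------------------

def read_metis(path: str | Path) -> Graph:
    """Read a METIS ``.graph`` file (1-based adjacency, header ``n m [fmt]``).

    Supported fmt codes: 0/000 (unweighted) and 1/001 (edge weights).
    Vertex-weighted variants are rejected.  Each undirected edge must be
    listed from both endpoints with consistent weight and is stored once.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln.strip() for ln in fh]
    body = [(i + 1, ln) for i, ln in enumerate(lines) if ln and not ln.startswith("%")]
    if not body:
        raise GraphFormatError(f"{path}: empty file")
    header = body[0][1].split()
    if len(header) not in (2, 3):
        raise GraphFormatError(f"{path}: bad header {body[0][1]!r}")
    try:
        n, m_decl = int(header[0]), int(header[1])
    except ValueError as exc:
        raise GraphFormatError(f"{path}: bad header {body[0][1]!r}") from exc
    fmt = header[2] if len(header) == 3 else "0"
    if fmt not in ("0", "000", "1", "001"):
        raise GraphFormatError(f"{path}: unsupported fmt code {fmt!r}")
    has_weights = fmt in ("1", "001")
    adj_lines = body[1:]
    if len(adj_lines) != n:
        raise GraphFormatError(
            f"{path}: header declares n={n} but found {len(adj_lines)} adjacency lines")

    edges: dict[tuple[int, int], float] = {}
    for u, (lineno, ln) in enumerate(adj_lines):
        toks = ln.split()
        if has_weights:
            if len(toks) % 2:
                raise GraphFormatError(f"{path}:{lineno}: odd token count in weighted line")
            pairs = [(toks[i], toks[i + 1]) for i in range(0, len(toks), 2)]
        else:
            pairs = [(t, "1") for t in toks]
        for vt, wt in pairs:
            try:
                v = int(vt) - 1
                w = float(wt)
            except ValueError as exc:
                raise GraphFormatError(f"{path}:{lineno}: bad token") from exc
            if not (0 <= v < n):
                raise GraphFormatError(f"{path}:{lineno}: neighbor {vt} out of range")
            if v == u:
                raise GraphFormatError(f"{path}:{lineno}: self-loop not valid in METIS")
            if w <= 0:
                raise GraphFormatError(f"{path}:{lineno}: non-positive weight {w}")
            key = (u, v) if u < v else (v, u)
            if key in edges:
                if edges[key] != w:
                    raise GraphFormatError(
                        f"{path}:{lineno}: asymmetric weight for edge {key}")
            else:
                edges[key] = w
    if len(edges) != m_decl:
        raise GraphFormatError(
            f"{path}: header declares m={m_decl} but found {len(edges)} distinct edges")
    return Graph.from_edges(n, ((u, v, w) for (u, v), w in edges.items()))


def write_metis(g: Graph, path: str | Path, weighted: bool = False) -> None:
    """Write METIS ``.graph``; rejects self-loops (not representable)."""
    if g.has_self_loops():
        raise ValueError("METIS format cannot represent self-loops")
    path = Path(path)
    nbrs: list[list[tuple[int, float]]] = [[] for _ in range(g.n)]
    for u, v, w in g.edges():
        nbrs[u].append((v, w))
        nbrs[v].append((u, w))
    with path.open("w") as fh:
        fmt = " 001" if weighted else ""
        fh.write(f"{g.n} {g.num_edges}{fmt}\n")
        for u in range(g.n):
            toks: list[str] = []
            for v, w in sorted(nbrs[u]):
                toks.append(str(v + 1))
                if weighted:
                    toks.append(f"{w:g}")
            fh.write(" ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# membership TSV
# ---------------------------------------------------------------------------

def write_membership(labels: np.ndarray, node_labels: Sequence, path: str | Path) -> None:
    """Write ``node<TAB>community`` with community ids renumbered 0..r-1 by
    first appearance over nodes in id order."""
    labels = np.asarray(labels)
    if len(labels) != len(node_labels):
        raise ValueError("partition does not cover all nodes")
    renum: dict[int, int] = {}
    path = Path(path)
    with path.open("w") as fh:
        for v, c in enumerate(labels):
            c = int(c)
            if c not in renum:
                renum[c] = len(renum)
            fh.write(f"{node_labels[v]}\t{renum[c]}\n")


def read_membership(path: str | Path, node_labels: Sequence) -> np.ndarray:
    """Read a membership TSV back into a label array aligned with
    ``node_labels`` (the graph's label map)."""
    path = Path(path)
    pos = {str(lab): i for i, lab in enumerate(node_labels)}
    out = np.full(len(node_labels), -1, dtype=np.int64)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split("\t") if "\t" in line else line.split()
            if len(toks) != 2:
                raise GraphFormatError(f"{path}:{lineno}: expected 2 columns")
            if toks[0] not in pos:
                raise GraphFormatError(f"{path}:{lineno}: unknown node {toks[0]!r}")
            out[pos[toks[0]]] = int(toks[1])
    if (out < 0).any():
        missing = [node_labels[i] for i in np.flatnonzero(out < 0)[:5]]
        raise GraphFormatError(f"{path}: nodes without membership, e.g. {missing}")
    return out
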