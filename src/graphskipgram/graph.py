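"""Graph container, edge-list / label / embedding file I/O, and graph generators.

The in-memory graph is a thin, immutable-ish wrapper over an undirected
simple graph: an ordered node list (which fixes embedding row indices),
a set of unordered edges with optional positive weights, and CSR adjacency
for the numerical routines.  Node identifiers are kept as strings; ordering
is numeric-aware so that files with integer ids get the natural row order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "LabelTable",
    "EmbeddingSet",
    "read_edgelist",
    "read_labels",
    "write_embeddings",
    "read_embeddings",
    "karate_fixture",
    "sbm_graph",
]


class GraphFormatError(ValueError):
    """Raised when an input file violates the expected text format."""


def _sort_key(node: str):
    # numeric-aware: integer ids sort numerically, everything else lexically
    try:
        return (0, int(node), node)
    except ValueError:
        return (1, 0, node)


@dataclass
class Graph:
    """Undirected simple graph with an ordered node set.

    Attributes
    ----------
    nodes:
        Node identifiers in their canonical (row) order.
    edges:
        Unordered edges as pairs of node *indices* ``(i, j)`` with ``i < j``.
    weights:
        Positive weight per edge, aligned with :attr:`edges`.  All 1.0 for
        unweighted graphs.
    weighted:
        Whether the graph carries meaningful edge weights (affects the
        weighted structure-information term only; walks ignore weights).
    block_of:
        Optional planted community label per node (set by :func:`sbm_graph`).
    """

    nodes: list[str]
    edges: list[tuple[int, int]]
    weights: np.ndarray
    weighted: bool = False
    block_of: dict[str, int] | None = None
    _index: dict[str, int] = field(init=False, repr=False)
    _adj: list[np.ndarray] = field(init=False, repr=False)
    _edge_weight: dict[tuple[int, int], float] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise ValueError("edge weights must be strictly positive")
        neigh: list[list[int]] = [[] for _ in self.nodes]
        self._edge_weight = {}
        for (i, j), w in zip(self.edges, self.weights):
            if i == j:
                raise ValueError("self-loops are not allowed")
            neigh[i].append(j)
            neigh[j].append(i)
            self._edge_weight[(i, j)] = float(w)
            self._edge_weight[(j, i)] = float(w)
        self._adj = [np.array(sorted(a), dtype=np.int64) for a in neigh]

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        extra_nodes: Iterable[str] = (),
        weighted: bool = False,
    ) -> "Graph":
        """Build a graph from string edges; collapses duplicates, drops loops."""
        nodeset: set[str] = set(str(n) for n in extra_nodes)
        seen: dict[tuple[str, str], float] = {}
        n_loops = 0
        n_dups = 0
        for e in edges:
            u, v = str(e[0]), str(e[1])
            w = float(e[2]) if len(e) == 3 else 1.0
            nodeset.update((u, v))
            if u == v:
                n_loops += 1
                continue
            key = (u, v) if _sort_key(u) <= _sort_key(v) else (v, u)
            if key in seen:
                n_dups += 1
                continue  # keep first weight
            seen[key] = w
        if n_loops:
            logger.info("dropped %d self-loop(s)", n_loops)
        if n_dups:
            warnings.warn(f"collapsed {n_dups} duplicate edge(s); kept first weight")
        nodes = sorted(nodeset, key=_sort_key)
        index = {n: i for i, n in enumerate(nodes)}
        idx_edges = sorted(
            (min(index[u], index[v]), max(index[u], index[v])) for u, v in seen
        )
        inv = {
            (min(index[u], index[v]), max(index[u], index[v])): w
            for (u, v), w in seen.items()
        }
        w_arr = np.array([inv[e] for e in idx_edges], dtype=float)
        return cls(nodes=nodes, edges=idx_edges, weights=w_arr, weighted=weighted)

    # -- queries ----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self, node: str) -> int:
        return self._index[str(node)]

    def __contains__(self, node: str) -> bool:
        return str(node) in self._index

    def neighbors(self, i: int) -> np.ndarray:
        """Neighbor indices of node index ``i`` (sorted)."""
        return self._adj[i]

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    def degrees(self) -> np.ndarray:
        return np.array([len(a) for a in self._adj], dtype=np.int64)

    def has_edge(self, i: int, j: int) -> bool:
        return (i, j) in self._edge_weight

    def edge_weight(self, i: int, j: int) -> float:
        return self._edge_weight[(i, j)]

    def adjacency_csr(self) -> sparse.csr_matrix:
        n = self.n_nodes
        if not self.edges:
            return sparse.csr_matrix((n, n))
        ij = np.array(self.edges, dtype=np.int64)
        rows = np.concatenate([ij[:, 0], ij[:, 1]])
        cols = np.concatenate([ij[:, 1], ij[:, 0]])
        data = np.concatenate([self.weights, self.weights])
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (i, j), w in zip(self.edges, self.weights):
            g.add_edge(self.nodes[i], self.nodes[j], weight=float(w))
        return g

    def is_connected(self) -> bool:
        if self.n_nodes == 0:
            return True
        n_comp, _ = sparse.csgraph.connected_components(
            self.adjacency_csr(), directed=False
        )
        return n_comp == 1

    def subgraph_without_edges(self, drop: Iterable[tuple[int, int]]) -> "Graph":
        """Copy of the graph with the given index edges removed (same node set)."""
        dropset = {(min(i, j), max(i, j)) for i, j in drop}
        kept = [
            (e, w) for e, w in zip(self.edges, self.weights) if e not in dropset
        ]
        edges = [e for e, _ in kept]
        weights = np.array([w for _, w in kept], dtype=float)
        return Graph(
            nodes=list(self.nodes),
            edges=edges,
            weights=weights,
            weighted=self.weighted,
            block_of=self.block_of,
        )


@dataclass
class LabelTable:
    """Multi-label assignment: node identifier -> non-empty set of labels."""

    labels: dict[str, set[str]]

    def __post_init__(self) -> None:
        for node, labs in self.labels.items():
            if not labs:
                raise ValueError(f"node {node!r} has an empty label set")

    def validate_against(self, g: Graph) -> None:
        missing = [n for n in self.labels if n not in g]
        if missing:
            raise ValueError(f"labeled nodes absent from graph: {missing[:5]}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class EmbeddingSet:
    """Paired input (``f``) and output (``f_out``) embedding matrices.

    Rows are aligned with ``node_index`` (the graph's canonical node order);
    ``f`` is the representation a node learns as walk center, ``f_out`` the
    one it learns as context.
    """

    node_index: list[str]
    f: np.ndarray
    f_out: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=np.float64)
        self.f_out = np.asarray(self.f_out, dtype=np.float64)
        if self.f.shape != self.f_out.shape:
            raise ValueError("f and f_out must have identical shape")
        if self.f.shape[0] != len(self.node_index):
            raise ValueError("row count does not match node index")
        if self.f.ndim != 2 or self.f.shape[1] < 1:
            raise ValueError("embedding dimension must be >= 1")

    @property
    def dim(self) -> int:
        return self.f.shape[1]


# -- file I/O -------------------------------------------------------------


def read_edgelist(path: str | Path, weighted: bool = False) -> Graph:
    """Read a whitespace-delimited edge list (``u v [w]``; ``#`` comments).

    Duplicate edges collapse to the first occurrence, self-loops are dropped
    (logged), and the graph is treated as undirected.
    """
    path = Path(path)
    edges: list[tuple] = []
    nodes: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            want = 3 if weighted else 2
            if len(tokens) != want:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected {want} tokens, got {len(tokens)}"
                )
            if weighted:
                try:
                    w = float(tokens[2])
                except ValueError as exc:
                    raise GraphFormatError(
                        f"{path}:{lineno}: bad weight {tokens[2]!r}"
                    ) from exc
                if w <= 0:
                    raise GraphFormatError(
                        f"{path}:{lineno}: non-positive weight {w}"
                    )
                if tokens[0] == tokens[1]:
                    nodes.append(tokens[0])
                    continue
                edges.append((tokens[0], tokens[1], w))
            else:
                if tokens[0] == tokens[1]:
                    nodes.append(tokens[0])
                    continue
                edges.append((tokens[0], tokens[1]))
    return Graph.from_edges(edges, extra_nodes=nodes, weighted=weighted)


def read_labels(path: str | Path) -> LabelTable:
    """Read a multi-label file: one line per node, ``node lab1 lab2 ...``."""
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: node with no labels"
                )
            table.setdefault(tokens[0], set()).update(tokens[1:])
    return LabelTable(labels=table)


def _write_matrix(nodes: Sequence[str], mat: np.ndarray, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{mat.shape[0]} {mat.shape[1]}\n")
        for node, row in zip(nodes, mat):
            fh.write(node + " " + " ".join(repr(float(x)) for x in row) + "\n")


def write_embeddings(
    emb: EmbeddingSet, which: str, path: str | Path
) -> list[Path]:
    """Write embeddings in the word2vec text dialect.

    ``which`` selects ``input`` (f), ``output`` (f_out) or ``both``; with
    ``both`` two files are written, ``<path>.input`` and ``<path>.output``.
    Returns the paths written.
    """
    path = Path(path)
    if which == "input":
        _write_matrix(emb.node_index, emb.f, path)
        return [path]
    if which == "output":
        _write_matrix(emb.node_index, emb.f_out, path)
        return [path]
    if which == "both":
        p_in = path.with_name(path.name + ".input")
        p_out = path.with_name(path.name + ".output")
        _write_matrix(emb.node_index, emb.f, p_in)
        _write_matrix(emb.node_index, emb.f_out, p_out)
        return [p_in, p_out]
    raise ValueError(f"which must be input/output/both, got {which!r}")


def read_embeddings(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read one word2vec-text matrix; returns ``(matrix, node order)``."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise GraphFormatError(f"{path}: malformed header")
        n, d = int(header[0]), int(header[1])
        nodes: list[str] = []
        rows = np.empty((n, d), dtype=float)
        count = 0
        for raw in fh:
            if not raw.strip():
                continue
            tokens = raw.split()
            if len(tokens) != d + 1:
                raise GraphFormatError(
                    f"{path}: row {count + 1} has {len(tokens) - 1} values, expected {d}"
                )
            if count >= n:
                raise GraphFormatError(f"{path}: more rows than header declares")
            nodes.append(tokens[0])
            rows[count] = [float(t) for t in tokens[1:]]
            count += 1
    if count != n:
        raise GraphFormatError(
            f"{path}: header declares {n} rows but {count} found"
        )
    return rows, nodes


# -- fixtures and generators ----------------------------------------------


def karate_fixture() -> Graph:
    """The 34-node Zachary karate-club graph (standard 1..34 numbering)."""
    ref = resources.files("graphskipgram.data") / "karate.edgelist"
    with resources.as_file(ref) as path:
        return read_edgelist(path)


def sbm_graph(
    block_sizes: Sequence[int],
    p_in: float,
    p_out: float,
    seed: int,
) -> Graph:
    """Stochastic-block-model graph with planted community labels.

    Emulates community-structured interaction networks: dense within-block
    wiring at rate ``p_in``, sparse between-block wiring at ``p_out``.
    Block labels are attached as ``Graph.block_of``.
    """
    if any(s <= 0 for s in block_sizes):
        raise ValueError("block sizes must be positive")
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("need 0 <= p_out < p_in <= 1")
    probs = [
        [p_in if i == j else p_out for j in range(len(block_sizes))]
        for i in range(len(block_sizes))
    ]
    g_nx = nx.stochastic_block_model(list(block_sizes), probs, seed=int(seed))
    edges = [(str(u), str(v)) for u, v in g_nx.edges()]
    all_nodes = [str(n) for n in g_nx.nodes()]
    g = Graph.from_edges(edges, extra_nodes=all_nodes)
    blocks: dict[str, int] = {}
    node = 0
    for b, size in enumerate(block_sizes):
        for _ in range(size):
            blocks[str(node)] = b
            node += 1
    g.block_of = blocks
    return g
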