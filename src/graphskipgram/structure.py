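"""Graph-structure information: degrees, shortest paths, and the closeness
function that modulates co-occurrence probabilities.

For a center node ``u`` and context node ``n`` the closeness is

    W(n, u) = w * clamp(D_u / D_n, [1, 1.1])
              + (1 - w) * max(0, 2 - 2 * P_un / p) ** a
              [+ w' * weight(u, n)   on weighted graphs, if the edge exists]

where ``D`` are node degrees, ``P_un`` the shortest-path length, ``p`` a
distance scale chosen just above the largest observed distance, and ``a`` an
exponent that spreads out concentrated distance distributions.  A reachability
indicator ``L`` (0 for identical or disconnected pairs, 1 otherwise) is used
as an exponent, ``W ** L``, so unreachable pairs contribute a neutral
multiplier of exactly 1.

Unreachable distances are stored as ``inf`` (never 0); the self-distance 0
maps to ``L = 0`` as well, so both degenerate cases deactivate W.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .graph import Graph

__all__ = [
    "StructureParams",
    "StructureInfo",
    "compute_degrees",
    "compute_shortest_paths",
    "estimate_distance_distribution",
    "choose_distance_scale",
    "reachability",
    "structure_weight",
    "structure_multipliers",
]

#: above this node count the full dense distance matrix is not materialized;
#: rows are computed per source on demand and LRU-cached instead
DENSE_P_THRESHOLD = 20_000


@dataclass(frozen=True)
class StructureParams:
    """Hyperparameters of the structure-information function.

    ``w``: mixing weight in (0,1) between the degree term and the distance
    term.  ``distance_scale_p``: scale > 1 chosen so all observed finite
    distances satisfy ``P_un <= p - 1``.  ``a``: exponent > 0 applied to the
    distance term.  ``w_prime``: additive coefficient on the edge weight for
    weighted graphs.  ``degree_ratio_bounds``: hard clamp interval for
    ``D_u / D_n``.
    """

    w: float = 0.8
    distance_scale_p: float = 5.0
    a: float = 1.0
    w_prime: float = 0.0
    degree_ratio_bounds: tuple[float, float] = (1.0, 1.1)

    def __post_init__(self) -> None:
        if not 0 < self.w < 1:
            raise ValueError("w must lie strictly in (0, 1)")
        if not self.distance_scale_p > 1:
            raise ValueError("distance_scale_p must exceed 1")
        if not self.a > 0:
            raise ValueError("a must be positive")
        if self.w_prime < 0:
            raise ValueError("w_prime must be nonnegative")
        lo, hi = self.degree_ratio_bounds
        if lo > hi:
            raise ValueError("degree_ratio_bounds must be ordered")


def compute_degrees(g: Graph) -> np.ndarray:
    """Incident-edge count per node, in canonical node order."""
    return g.degrees()


def compute_shortest_paths(
    g: Graph, sources: Sequence[int] | None = None
) -> np.ndarray:
    """Shortest-path lengths from ``sources`` (default: all nodes).

    Dijkstra on the weighted adjacency; on unweighted graphs (all weights 1)
    this yields hop counts.  Unreachable pairs are ``inf``.
    """
    csr = g.adjacency_csr()
    if sources is None:
        return dijkstra(csr, directed=False)
    return dijkstra(csr, directed=False, indices=list(sources))


def estimate_distance_distribution(
    g: Graph, n_source_samples: int, seed: int
) -> dict[int, float]:
    """Histogram of finite inter-node distances from sampled source nodes.

    Samples ``n_source_samples`` sources without replacement (all nodes when
    the request covers the graph), runs single-source shortest paths from
    each, and normalizes the counts of finite positive distances.
    """
    if g.n_nodes == 0:
        raise ValueError("cannot sample distances from an empty graph")
    if n_source_samples < 1:
        raise ValueError("need at least one source sample")
    rng = np.random.default_rng(seed)
    n = g.n_nodes
    if n_source_samples >= n:
        sources = np.arange(n)
    else:
        sources = rng.choice(n, size=n_source_samples, replace=False)
    dist = compute_shortest_paths(g, sources=sources)
    finite = dist[np.isfinite(dist) & (dist > 0)]
    values, counts = np.unique(finite.astype(np.int64), return_counts=True)
    total = counts.sum()
    if total == 0:
        return {}
    return {int(v): float(c) / float(total) for v, c in zip(values, counts)}


def choose_distance_scale(hist: Mapping[int, float]) -> float:
    """Distance scale p = (max observed finite distance) + 1.

    Guarantees every reachable pair has ``P_un <= p - 1`` so the distance
    term ``2 - 2 P_un / p`` stays strictly positive.
    """
    if not hist:
        raise ValueError("empty distance histogram")
    return float(max(hist)) + 1.0


def reachability(p_un: float) -> int:
    """Reachability indicator L from a stored distance.

    0 when the pair is identical (distance 0) or disconnected (``inf``);
    1 for any finite positive distance.  Positively sampled walk pairs are
    always reachable, so the walk-sampling override is a no-op here.
    """
    if p_un == 0 or not np.isfinite(p_un):
        return 0
    return 1


class StructureInfo:
    """Precomputed degree vector and (possibly lazy) distance matrix.

    Below :data:`DENSE_P_THRESHOLD` nodes the full distance matrix is held
    dense; above it, rows are computed per source on demand and cached.
    """

    def __init__(self, g: Graph, params: StructureParams | None = None):
        self.graph = g
        self.params = params or StructureParams()
        self.D = compute_degrees(g)
        self._dense: np.ndarray | None = None
        if g.n_nodes <= DENSE_P_THRESHOLD:
            self._dense = compute_shortest_paths(g)
        self._row_cached = lru_cache(maxsize=1024)(self._row_uncached)

    def _row_uncached(self, i: int) -> np.ndarray:
        return compute_shortest_paths(self.graph, sources=[i])[0]

    def distance_row(self, i: int) -> np.ndarray:
        if self._dense is not None:
            return self._dense[i]
        return self._row_cached(i)

    def distance(self, u: int, n: int) -> float:
        return float(self.distance_row(u)[n])

    @property
    def P(self) -> np.ndarray:
        """Dense distance matrix (only available below the size threshold)."""
        if self._dense is None:
            raise MemoryError(
                "dense distance matrix disabled for graphs above "
                f"{DENSE_P_THRESHOLD} nodes; use distance_row()"
            )
        return self._dense

    def L(self, u: int, n: int) -> int:
        return reachability(self.distance(u, n))


def structure_weight(u: int, n: int, info: StructureInfo, g: Graph) -> float:
    """Closeness W(n, u) between context ``n`` and center ``u`` (indices).

    Callers must only ask for reachable pairs (L = 1); unreachable pairs get
    the neutral multiplier 1 through the ``W ** L`` exponent and must not be
    evaluated here.
    """
    p_un = info.distance(u, n)
    if reachability(p_un) == 0:
        raise ValueError(
            f"W requested for unreachable or identical pair ({u}, {n})"
        )
    prm = info.params
    lo, hi = prm.degree_ratio_bounds
    ratio = float(np.clip(info.D[u] / info.D[n], lo, hi))
    base = max(0.0, 2.0 - 2.0 * p_un / prm.distance_scale_p)
    w_val = prm.w * ratio + (1.0 - prm.w) * base ** prm.a
    if g.weighted and prm.w_prime > 0 and g.has_edge(u, n):
        w_val += prm.w_prime * g.edge_weight(u, n)
    return w_val


def structure_multipliers(g: Graph, info: StructureInfo) -> np.ndarray:
    """Dense matrix M[u, n] = W(n, u) ** L(n, u) for all node pairs.

    Rows index the center node, columns the context node.  Unreachable and
    diagonal entries are exactly 1 (neutral).  Used by the trainer to look up
    the structure multiplier per sampled pair.
    """
    n = g.n_nodes
    P = info.P  # dense path only; training graphs are small
    prm = info.params
    D = info.D.astype(float)
    lo, hi = prm.degree_ratio_bounds
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.clip(D[:, None] / D[None, :], lo, hi)  # [u, n] = D_u / D_n
    with np.errstate(invalid="ignore"):
        base = np.maximum(0.0, 2.0 - 2.0 * P / prm.distance_scale_p)
    base = np.where(np.isfinite(P), base, 0.0)
    M = prm.w * ratio + (1.0 - prm.w) * base ** prm.a
    if g.weighted and prm.w_prime > 0:
        Wmat = g.adjacency_csr().toarray()
        M = M + prm.w_prime * Wmat
    L = np.isfinite(P) & (P > 0)
    M = np.where(L, M, 1.0)
    return M
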