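"""Random-walk corpus generation and (center, context) pair sampling.

Walks follow the standard truncated-random-walk recipe: ``r`` walks of length
``t`` start from every node, with the start order reshuffled each pass.  The
``uniform`` strategy picks a uniformly random neighbor each step; the
``biased`` strategy applies second-order return/in-out transition weights
(1/p to step back, 1 to a common neighbor of the previous node, 1/q
otherwise).  Training pairs are drawn with a per-position shrinking window:
an effective radius is sampled uniformly from {1..m}, the word2vec
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .graph import Graph

__all__ = ["WalkConfig", "WalkCorpus", "generate_walks", "context_pairs"]


@dataclass(frozen=True)
class WalkConfig:
    """Walk-corpus settings: ``walks_per_node`` (r), ``walk_length`` (t),
    ``window`` (m), strategy, and node2vec-style return/in-out parameters."""

    walks_per_node: int = 80
    walk_length: int = 10
    window: int = 10
    strategy: str = "uniform"
    return_p: float = 1.0
    inout_q: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.walks_per_node, self.walk_length, self.window) < 1:
            raise ValueError("r, t and m must all be >= 1")
        if self.strategy not in ("uniform", "biased"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "biased" and min(self.return_p, self.inout_q) <= 0:
            raise ValueError("biased strategy needs return_p, inout_q > 0")


@dataclass
class WalkCorpus:
    """Materialized walks over node *indices* of the originating graph."""

    walks: list[np.ndarray]
    n_nodes: int

    def node_frequencies(self) -> np.ndarray:
        """Occurrence count of each node index across all walks."""
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        for walk in self.walks:
            counts += np.bincount(walk, minlength=self.n_nodes)
        return counts

    def __len__(self) -> int:
        return len(self.walks)


def _uniform_walk(g: Graph, start: int, t: int, rng: np.random.Generator) -> np.ndarray:
    walk = np.empty(t, dtype=np.int64)
    walk[0] = start
    cur = start
    for i in range(1, t):
        nbrs = g.neighbors(cur)
        if len(nbrs) == 0:
            return walk[:i]
        cur = nbrs[rng.integers(len(nbrs))]
        walk[i] = cur
    return walk


def _biased_walk(
    g: Graph, start: int, t: int, p: float, q: float, rng: np.random.Generator
) -> np.ndarray:
    walk = np.empty(t, dtype=np.int64)
    walk[0] = start
    nbrs = g.neighbors(start)
    if t == 1 or len(nbrs) == 0:
        return walk[:1]
    walk[1] = nbrs[rng.integers(len(nbrs))]
    for i in range(2, t):
        prev, cur = walk[i - 2], walk[i - 1]
        nbrs = g.neighbors(cur)
        if len(nbrs) == 0:
            return walk[:i]
        weights = np.empty(len(nbrs), dtype=float)
        prev_nbrs = g.neighbors(prev)
        for j, x in enumerate(nbrs):
            if x == prev:
                weights[j] = 1.0 / p
            elif np.searchsorted(prev_nbrs, x) < len(prev_nbrs) and prev_nbrs[
                np.searchsorted(prev_nbrs, x)
            ] == x:
                weights[j] = 1.0
            else:
                weights[j] = 1.0 / q
        weights /= weights.sum()
        walk[i] = nbrs[rng.choice(len(nbrs), p=weights)]
    return walk


def generate_walks(g: Graph, cfg: WalkConfig) -> WalkCorpus:
    """Generate ``r`` truncated random walks per node, deterministically."""
    if g.n_nodes == 0:
        raise ValueError("cannot walk on an empty graph")
    rng = np.random.default_rng(cfg.seed)
    walks: list[np.ndarray] = []
    order = np.arange(g.n_nodes)
    for _ in range(cfg.walks_per_node):
        rng.shuffle(order)
        for start in order:
            if cfg.strategy == "uniform":
                walks.append(_uniform_walk(g, int(start), cfg.walk_length, rng))
            else:
                walks.append(
                    _biased_walk(
                        g, int(start), cfg.walk_length,
                        cfg.return_p, cfg.inout_q, rng,
                    )
                )
    return WalkCorpus(walks=walks, n_nodes=g.n_nodes)


def context_pairs(
    corpus: WalkCorpus, m: int, seed: int = 0, shrink: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """(center, context) index pairs from every walk position.

    With ``shrink=True`` an effective radius b is drawn uniformly from
    {1..m} per position; otherwise b = m.  Pairs whose members are the same
    node (walks can revisit) are skipped.  Returns two aligned int arrays.
    """
    if m < 1:
        raise ValueError("window must be >= 1")
    rng = np.random.default_rng(seed)
    centers: list[int] = []
    contexts: list[int] = []
    for walk in corpus.walks:
        t = len(walk)
        if t < 2:
            continue
        radii = rng.integers(1, m + 1, size=t) if shrink else np.full(t, m)
        for i in range(t):
            b = int(radii[i])
            lo = max(0, i - b)
            hi = min(t, i + b + 1)
            for j in range(lo, hi):
                if j == i or walk[j] == walk[i]:
                    continue
                centers.append(int(walk[i]))
                contexts.append(int(walk[j]))
    return (
        np.asarray(centers, dtype=np.int64),
        np.asarray(contexts, dtype=np.int64),
    )
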