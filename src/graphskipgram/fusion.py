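"""Selective input/output embedding fusion ("Fioepn").

After skip-gram training every node owns two vectors that should largely
agree.  The nodes whose input and output rows agree *least* are the ones
whose input embedding is likely undertrained; for the fraction ``p`` of
lowest-similarity nodes the fused representation is the elementwise mean
``(f + f_out) / 2``, while all other nodes keep their input row unchanged.

Cosine similarity is the default score (scale-invariant across the two
differently-initialized matrices); the raw dot product is selectable.
Fusion is not idempotent — fusing twice re-averages — so callers fuse once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph import EmbeddingSet

__all__ = ["FusionConfig", "similarity_scores", "fioepn"]


@dataclass(frozen=True)
class FusionConfig:
    """``fusion_ratio`` in [0, 1]: fraction of lowest-similarity nodes to
    fuse; ``similarity``: "cosine" or "dot"."""

    fusion_ratio: float = 0.10
    similarity: str = "cosine"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fusion_ratio <= 1.0:
            raise ValueError("fusion_ratio must lie in [0, 1]")
        if self.similarity not in ("cosine", "dot"):
            raise ValueError(f"unknown similarity {self.similarity!r}")


def similarity_scores(emb: EmbeddingSet, kind: str = "cosine") -> np.ndarray:
    """Per-node agreement between the input and output rows.

    ``cosine`` normalizes by the row norms (rows with zero norm score 0);
    ``dot`` is the raw inner product.
    """
    dots = np.einsum("ij,ij->i", emb.f, emb.f_out)
    if kind == "dot":
        return dots
    if kind == "cosine":
        norms = np.linalg.norm(emb.f, axis=1) * np.linalg.norm(emb.f_out, axis=1)
        out = np.zeros_like(dots)
        nz = norms > 0
        out[nz] = dots[nz] / norms[nz]
        return out
    raise ValueError(f"unknown similarity {kind!r}")


def fioepn(emb: EmbeddingSet, cfg: FusionConfig = FusionConfig()) -> np.ndarray:
    """Fused input matrix f*: averages f and f_out for the lowest-scoring
    fraction of nodes, leaves every other row of f untouched.

    The threshold is the score at sorted index ``floor(ratio * |V|)``
    (clamped to the last index); only nodes *strictly below* it fuse, so
    ratio 0 is the identity and score ties at the threshold are excluded.
    The input EmbeddingSet is not mutated.
    """
    scores = similarity_scores(emb, cfg.similarity)
    n = scores.shape[0]
    fused = emb.f.copy()
    if n == 0 or cfg.fusion_ratio == 0.0:
        return fused
    idx = min(int(math.floor(cfg.fusion_ratio * n)), n - 1)
    sim = np.sort(scores)[idx]
    mask = scores < sim
    fused[mask] = (emb.f[mask] + emb.f_out[mask]) / 2.0
    return fused
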