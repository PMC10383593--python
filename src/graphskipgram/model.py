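"""Skip-gram training with negative sampling, in two modes.

``vanilla`` is the classic skip-gram-with-negative-sampling update on
random-walk pairs.  ``graph`` rescales the co-occurrence probability of each
(center u, context n) pair by the structure closeness ``W(n, u) ** L(n, u)``
computed in :mod:`graphskipgram.structure`:

    A(n, u) = clip(sigmoid(f_out[n] . f[u]) * W(n, u) ** L, -1, 1)

The SGD step follows the classic asymmetric scheme: per positive pair, the
gradient scalar is ``g = (label - A) * lr``; the context row ``f_out[n]``
moves toward the center row, an error accumulator collects ``f_out[n] * g``
over the positive pair and its k negative draws, and the center row ``f[u]``
is moved once by the accumulated error.  In graph mode both row updates are
additionally scaled by ``W ** L`` (W treated as a constant multiplier of the
co-occurrence probability).  With all multipliers equal to 1 the graph-mode
arithmetic is bit-for-bit the vanilla arithmetic.

The inner loop is JIT-compiled with numba when available; the pure-Python
twin executes the identical floating-point operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph import EmbeddingSet, Graph
from .structure import StructureInfo, structure_multipliers
from .walks import WalkConfig, WalkCorpus, context_pairs, generate_walks

__all__ = [
    "TrainConfig",
    "NoiseDistribution",
    "SamplingStats",
    "init_embeddings",
    "build_noise_distribution",
    "co_occurrence_score",
    "log_score_gradient",
    "pair_update",
    "train",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training settings: embedding dimension ``dim``, negatives per positive
    ``negatives`` (k), initial learning rate ``alpha0`` with linear decay,
    ``mode`` (vanilla or graph), and the noise-distribution exponent."""

    dim: int = 128
    negatives: int = 5
    alpha0: float = 0.025
    mode: str = "vanilla"
    noise_exponent: float = 0.75
    shrink_window: bool = True
    w_inside_sigmoid: bool = False
    stats_enabled: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.negatives < 0:
            raise ValueError("negatives must be >= 0")
        if not 0 < self.alpha0 <= 1:
            raise ValueError("alpha0 must lie in (0, 1]")
        if self.mode not in ("vanilla", "graph"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class NoiseDistribution:
    """Unigram noise distribution over node indices (probabilities sum to 1)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < 0) or not math.isclose(
            self.probs.sum(), 1.0, abs_tol=1e-9
        ):
            raise ValueError("probabilities must be nonnegative and sum to 1")
        self._cum = np.cumsum(self.probs)

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        return np.searchsorted(self._cum, rng.random(size), side="right")


@dataclass
class SamplingStats:
    """Per-node counts of appearances as center (PosV), context (PosC) and
    negative draw (Neg) over one training run."""

    pos_v: np.ndarray
    pos_c: np.ndarray
    neg: np.ndarray


def init_embeddings(n_nodes: int, d: int, seed: int) -> EmbeddingSet:
    """Random-uniform input embeddings in [-0.5/d, 0.5/d]; zero output
    embeddings (the asymmetric init that accelerates early training)."""
    rng = np.random.default_rng(seed)
    f = rng.uniform(-0.5 / d, 0.5 / d, size=(n_nodes, d))
    return EmbeddingSet(
        node_index=[str(i) for i in range(n_nodes)],
        f=f,
        f_out=np.zeros((n_nodes, d)),
    )


def build_noise_distribution(
    corpus: WalkCorpus, exponent: float = 0.75
) -> NoiseDistribution:
    """Node probability proportional to corpus frequency ** exponent."""
    counts = corpus.node_frequencies().astype(float)
    if counts.sum() == 0:
        raise ValueError("empty corpus")
    raised = np.where(counts > 0, counts ** exponent, 0.0)
    return NoiseDistribution(probs=raised / raised.sum())


def _sigmoid(x: float) -> float:
    if x > 30.0:
        return 1.0
    if x < -30.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


def co_occurrence_score(
    f_u: np.ndarray, fout_n: np.ndarray, W: float = 1.0, L: int = 1
) -> float:
    """Clipped co-occurrence score A = clip(sigmoid(f_out . f) * W**L, -1, 1)."""
    s = float(np.dot(fout_n, f_u))
    a = _sigmoid(s) * W ** L
    return float(min(1.0, max(-1.0, a)))


def log_score_gradient(
    f_u: np.ndarray,
    fout_n: np.ndarray,
    positive: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of log A w.r.t. (f_u, fout_n), pre-clipping.

    For the positive term log A(f_out, f) = log sigmoid(s) + L log W the
    structure multiplier contributes only a constant, so the gradient is
    (1 - sigmoid(s)) times the partner vector; for the negative term
    log A(-f_out, f) it is -sigmoid(s) times the partner vector.
    """
    s = float(np.dot(fout_n, f_u))
    coef = (1.0 - _sigmoid(s)) if positive else -_sigmoid(s)
    return coef * fout_n, coef * f_u


def pair_update(
    u: int,
    n: int,
    label: int,
    emb: EmbeddingSet,
    lr: float,
    multiplier: float = 1.0,
    accumulator: np.ndarray | None = None,
    w_inside_sigmoid: bool = False,
) -> np.ndarray:
    """One context-row update; returns the updated error accumulator.

    ``multiplier`` is ``W(n, u) ** L`` (1.0 in vanilla mode).  The context
    row ``f_out[n]`` is updated in place; the center row ``f[u]`` is not
    touched — callers apply the accumulator to it after the positive pair
    and its negatives are processed.
    """
    if accumulator is None:
        accumulator = np.zeros(emb.dim)
    s = float(np.dot(emb.f_out[n], emb.f[u]))
    if w_inside_sigmoid:
        a = _sigmoid(s * multiplier)
    else:
        a = min(1.0, max(-1.0, _sigmoid(s) * multiplier))
    g = (label - a) * lr * multiplier
    accumulator = accumulator + emb.f_out[n] * g
    emb.f_out[n] = emb.f_out[n] + emb.f[u] * g
    return accumulator


def _sgd_loop_py(f, f_out, centers, contexts, negatives, mult_pos, mult_neg,
                 lrs, inside):
    """Inner SGD loop; numba-jitted twin below executes identical arithmetic."""
    n_pairs = centers.shape[0]
    d = f.shape[1]
    k = negatives.shape[1]
    for i in range(n_pairs):
        u = centers[i]
        lr = lrs[i]
        neule = np.zeros(d)
        # positive pair
        n = contexts[i]
        s = 0.0
        for j in range(d):
            s += f_out[n, j] * f[u, j]
        m = mult_pos[i]
        if inside:
            a = _sigmoid(s * m)
        else:
            a = _sigmoid(s) * m
            if a > 1.0:
                a = 1.0
            elif a < -1.0:
                a = -1.0
        g = (1.0 - a) * lr * m
        for j in range(d):
            neule[j] += f_out[n, j] * g
            f_out[n, j] += f[u, j] * g
        # negative draws
        for q in range(k):
            n = negatives[i, q]
            s = 0.0
            for j in range(d):
                s += f_out[n, j] * f[u, j]
            m = mult_neg[i, q]
            if inside:
                a = _sigmoid(s * m)
            else:
                a = _sigmoid(s) * m
                if a > 1.0:
                    a = 1.0
                elif a < -1.0:
                    a = -1.0
            g = (0.0 - a) * lr * m
            for j in range(d):
                neule[j] += f_out[n, j] * g
                f_out[n, j] += f[u, j] * g
        for j in range(d):
            f[u, j] += neule[j]


try:  # pragma: no cover - exercised indirectly
    import numba

    _sigmoid = numba.njit(cache=False)(_sigmoid)  # type: ignore[assignment]
    _sgd_loop = numba.njit(cache=False)(_sgd_loop_py)
except Exception:  # pragma: no cover
    _sgd_loop = _sgd_loop_py


def _draw_negatives(
    noise: NoiseDistribution,
    centers: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """k noise draws per pair; draws equal to the center are resampled
    (duplicates among the k draws are allowed, the word2vec convention)."""
    n_pairs = centers.shape[0]
    draws = noise.sample(rng, (n_pairs, k))
    if k == 0:
        return draws
    for _ in range(200):
        mask = draws == centers[:, None]
        n_bad = int(mask.sum())
        if n_bad == 0:
            break
        draws[mask] = noise.sample(rng, n_bad)
    return draws


def train(
    g: Graph,
    wcfg: WalkConfig,
    tcfg: TrainConfig,
    info: StructureInfo | None = None,
    structure_matrix: np.ndarray | None = None,
    collect_stats: bool = False,
):
    """Full training pipeline: walks -> pairs -> negative-sampling SGD.

    Graph mode requires either a :class:`StructureInfo` (from which the
    dense multiplier matrix ``W ** L`` is built) or an explicit
    ``structure_matrix`` override.  The learning rate decays linearly from
    ``alpha0`` to ``alpha0 * 1e-4`` over the pair budget.  Single-threaded
    and bit-reproducible given the two config seeds.

    Returns the trained :class:`EmbeddingSet`, or ``(emb, SamplingStats)``
    when ``collect_stats`` (or ``tcfg.stats_enabled``) is set.
    """
    if tcfg.mode == "graph":
        if structure_matrix is None:
            if info is None:
                raise ValueError(
                    "graph mode needs a StructureInfo or structure_matrix"
                )
            structure_matrix = structure_multipliers(g, info)
    corpus = generate_walks(g, wcfg)
    wseed = np.random.SeedSequence([wcfg.seed, 1]).generate_state(1)[0]
    centers, contexts = context_pairs(
        corpus, wcfg.window, seed=int(wseed), shrink=tcfg.shrink_window
    )
    n_pairs = centers.shape[0]
    ss = np.random.SeedSequence(tcfg.seed)
    init_seed, neg_seed = (int(s) for s in ss.generate_state(2))
    emb = init_embeddings(g.n_nodes, tcfg.dim, init_seed)
    emb.node_index = list(g.nodes)
    if n_pairs == 0:
        if collect_stats or tcfg.stats_enabled:
            z = np.zeros(g.n_nodes, dtype=np.int64)
            return emb, SamplingStats(z.copy(), z.copy(), z.copy())
        return emb

    noise = build_noise_distribution(corpus, tcfg.noise_exponent)
    rng = np.random.default_rng(neg_seed)
    negatives = _draw_negatives(noise, centers, tcfg.negatives, rng)

    if tcfg.mode == "graph":
        mult_pos = structure_matrix[centers, contexts]
        mult_neg = (
            structure_matrix[centers[:, None], negatives]
            if tcfg.negatives > 0
            else np.ones((n_pairs, 0))
        )
    else:
        mult_pos = np.ones(n_pairs)
        mult_neg = np.ones((n_pairs, tcfg.negatives))

    lrs = tcfg.alpha0 * np.maximum(1e-4, 1.0 - np.arange(n_pairs) / n_pairs)
    _sgd_loop(
        emb.f,
        emb.f_out,
        centers,
        contexts,
        np.ascontiguousarray(negatives, dtype=np.int64),
        np.ascontiguousarray(mult_pos, dtype=np.float64),
        np.ascontiguousarray(mult_neg, dtype=np.float64),
        lrs,
        tcfg.w_inside_sigmoid,
    )
    if not np.all(np.isfinite(emb.f)) or not np.all(np.isfinite(emb.f_out)):
        raise FloatingPointError("training produced non-finite values")
    if collect_stats or tcfg.stats_enabled:
        stats = SamplingStats(
            pos_v=np.bincount(centers, minlength=g.n_nodes),
            pos_c=np.bincount(contexts, minlength=g.n_nodes),
            neg=np.bincount(negatives.ravel(), minlength=g.n_nodes),
        )
        return emb, stats
    return emb
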