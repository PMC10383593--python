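"""Evaluation surfaces: clustering quality against modularity classes,
multi-label node classification, and link prediction with edge operators.

Clustering quality is measured by the Calinski-Harabasz index

    CH = [BGSS / (K - 1)] / [WGSS / (n - K)]

and by the per-class within-group sum of squares WGSS(c), both computed
directly from the embedding matrix and a hard partition.  Multi-label
classification follows the standard protocol for walk-based embeddings:
one-vs-rest logistic regression on a random train fraction, predicting each
test node's top-k labels where k is its true label count, scored by
micro-F1 averaged over repeats.  Link prediction removes a fraction of
edges while keeping the residual graph connected, re-embeds the residual
graph, and classifies edge features built with symmetric per-dimension
operators (average, Hadamard, |diff|, diff^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from networkx.algorithms.community import greedy_modularity_communities
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .graph import Graph, LabelTable

__all__ = [
    "EvalResult",
    "modularity_classes",
    "wgss",
    "calinski_harabasz",
    "multilabel_eval",
    "edge_features",
    "link_prediction_eval",
]

EDGE_OPERATORS = ("average", "hadamard", "weighted_l1", "weighted_l2")


@dataclass
class EvalResult:
    """Collected evaluation scores (fractions in [0, 1] internally)."""

    micro_f1: dict[float, float] = field(default_factory=dict)
    lp_accuracy: dict[str, float] = field(default_factory=dict)
    ch: float | None = None
    wgss: dict[int, float] = field(default_factory=dict)
    repeats: int = 1


def modularity_classes(g: Graph) -> dict[str, int]:
    """Greedy modularity-maximization partition, node -> class index.

    Classes are numbered 1..K ordered by decreasing size (ties broken by the
    smallest contained node index), so "class 3" is well defined.
    """
    communities = greedy_modularity_communities(g.to_networkx())
    comms = [sorted(c, key=g.index) for c in communities]
    comms.sort(key=lambda c: (-len(c), g.index(c[0])))
    out: dict[str, int] = {}
    for label, members in enumerate(comms, start=1):
        for node in members:
            out[node] = label
    return out


def _group_rows(
    emb: np.ndarray, labels: Sequence
) -> dict[object, np.ndarray]:
    labels = list(labels)
    if len(labels) != emb.shape[0]:
        raise ValueError("one label per embedding row required")
    groups: dict[object, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return {lab: emb[rows] for lab, rows in groups.items()}


def wgss(emb: np.ndarray, labels: Sequence) -> dict[object, float]:
    """Within-group sum of squares per class: sum_i ||x_i - centroid_c||^2."""
    emb = np.asarray(emb, dtype=float)
    out: dict[object, float] = {}
    for lab, rows in _group_rows(emb, labels).items():
        centroid = rows.mean(axis=0)
        out[lab] = float(((rows - centroid) ** 2).sum())
    return out


def calinski_harabasz(emb: np.ndarray, labels: Sequence) -> float:
    """Calinski-Harabasz index (between/within dispersion ratio)."""
    emb = np.asarray(emb, dtype=float)
    groups = _group_rows(emb, labels)
    k = len(groups)
    n = emb.shape[0]
    if k < 2:
        raise ValueError("CH needs at least two classes")
    if n <= k:
        raise ValueError("CH needs more points than classes")
    overall = emb.mean(axis=0)
    bgss = 0.0
    wg = 0.0
    for rows in groups.values():
        centroid = rows.mean(axis=0)
        bgss += len(rows) * float(((centroid - overall) ** 2).sum())
        wg += float(((rows - centroid) ** 2).sum())
    if wg == 0.0:
        return float("inf")
    return (bgss / (k - 1)) / (wg / (n - k))


def _top_k_predictions(scores: np.ndarray, k_per_row: np.ndarray) -> np.ndarray:
    pred = np.zeros_like(scores, dtype=int)
    for i, k in enumerate(k_per_row):
        if k > 0:
            top = np.argsort(scores[i])[::-1][:k]
            pred[i, top] = 1
    return pred


def _micro_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2 * tp / denom


def multilabel_eval(
    emb: np.ndarray,
    node_index: Sequence[str],
    labels: LabelTable,
    train_fraction: float,
    repeats: int = 10,
    seed: int = 0,
    top_k_rule: bool = True,
) -> float:
    """Mean micro-F1 of one-vs-rest logistic regression over random splits.

    With ``top_k_rule`` each test node receives its top-k_i scored labels,
    k_i being its true label count; otherwise a plain 0.5 threshold is used.
    Labels absent from a training split are skipped with a warning.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly in (0, 1)")
    idx_of = {n: i for i, n in enumerate(node_index)}
    nodes = [n for n in node_index if n in labels.labels]
    label_names = sorted({l for n in nodes for l in labels.labels[n]})
    lab_col = {l: j for j, l in enumerate(label_names)}
    X = np.asarray(emb, dtype=float)[[idx_of[n] for n in nodes]]
    Y = np.zeros((len(nodes), len(label_names)), dtype=int)
    for i, n in enumerate(nodes):
        for l in labels.labels[n]:
            Y[i, lab_col[l]] = 1
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(repeats):
        perm = rng.permutation(len(nodes))
        n_train = max(1, int(round(train_fraction * len(nodes))))
        tr, te = perm[:n_train], perm[n_train:]
        if len(te) == 0:
            raise ValueError("train_fraction leaves no test nodes")
        prob = np.zeros((len(te), len(label_names)))
        for j in range(len(label_names)):
            col = Y[tr, j]
            if col.min() == col.max():
                warnings.warn(
                    f"label {label_names[j]!r} constant in a training split; skipped"
                )
                prob[:, j] = float(col.max())
                continue
            clf = LogisticRegression(C=1.0, max_iter=1000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(X[tr], col)
            prob[:, j] = clf.predict_proba(X[te])[:, 1]
        if top_k_rule:
            pred = _top_k_predictions(prob, Y[te].sum(axis=1))
        else:
            pred = (prob >= 0.5).astype(int)
        scores.append(_micro_f1(Y[te], pred))
    return float(np.mean(scores))


def edge_features(
    f: np.ndarray, u: int, v: int, operator: str
) -> np.ndarray:
    """Symmetric per-dimension edge feature vector for node indices u, v."""
    fu, fv = np.asarray(f[u], dtype=float), np.asarray(f[v], dtype=float)
    if operator == "average":
        return (fu + fv) / 2.0
    if operator == "hadamard":
        return fu * fv
    if operator == "weighted_l1":
        return np.abs(fu - fv)
    if operator == "weighted_l2":
        return (fu - fv) ** 2
    raise ValueError(f"unknown operator {operator!r}; choose {EDGE_OPERATORS}")


def _remove_edges_keep_connected(
    g: Graph, fraction: float, rng: np.random.Generator
) -> tuple[Graph, list[tuple[int, int]]]:
    target = int(round(fraction * g.n_edges))
    order = rng.permutation(g.n_edges)
    residual = g
    removed: list[tuple[int, int]] = []
    for ei in order:
        if len(removed) >= target:
            break
        edge = g.edges[int(ei)]
        if edge not in residual.edges:
            continue
        candidate = residual.subgraph_without_edges([edge])
        if candidate.is_connected():
            residual = candidate
            removed.append(edge)
    if len(removed) < target:
        warnings.warn(
            f"only {len(removed)}/{target} edges removable while keeping "
            "the residual graph connected"
        )
    return residual, removed


def _sample_nonedges(
    g: Graph, count: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    n = g.n_nodes
    guard = 0
    while len(out) < count and guard < 100 * count + 1000:
        guard += 1
        i, j = int(rng.integers(n)), int(rng.integers(n))
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in seen or g.has_edge(*key):
            continue
        seen.add(key)
        out.append(key)
    if len(out) < count:
        raise ValueError("graph too dense to sample the requested non-edges")
    return out


def link_prediction_eval(
    g: Graph,
    embed: Callable[[Graph], np.ndarray],
    removal_fraction: float = 0.5,
    operator: str = "hadamard",
    seed: int = 0,
) -> float:
    """Link-prediction test accuracy with a connectivity-preserving split.

    Removes ``removal_fraction`` of the edges one at a time, rejecting any
    removal that would disconnect the residual graph.  ``embed`` maps the
    residual graph to an input-embedding matrix.  Training positives are a
    residual-edge sample the size of the removed set, test positives are the
    removed edges; negatives are sampled non-edges in equal number.  A
    logistic-regression classifier on the edge features yields the test
    accuracy.
    """
    if not 0 < removal_fraction < 1:
        raise ValueError("removal_fraction must lie strictly in (0, 1)")
    if not g.is_connected():
        raise ValueError("link prediction expects a connected graph")
    rng = np.random.default_rng(seed)
    residual, removed = _remove_edges_keep_connected(g, removal_fraction, rng)
    if not removed:
        raise ValueError("no edge could be removed while staying connected")
    f = np.asarray(embed(residual), dtype=float)

    n_test = len(removed)
    res_edges = [residual.edges[int(i)] for i in
                 rng.choice(residual.n_edges, size=min(n_test, residual.n_edges),
                            replace=False)]
    neg = _sample_nonedges(g, n_test + len(res_edges), rng)
    neg_train, neg_test = neg[: len(res_edges)], neg[len(res_edges):]

    def feats(pairs):
        return np.array([edge_features(f, i, j, operator) for i, j in pairs])

    X_tr = np.vstack([feats(res_edges), feats(neg_train)])
    y_tr = np.concatenate([np.ones(len(res_edges)), np.zeros(len(neg_train))])
    X_te = np.vstack([feats(removed), feats(neg_test)])
    y_te = np.concatenate([np.ones(len(removed)), np.zeros(len(neg_test))])
    clf = LogisticRegression(C=1.0, max_iter=1000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X_tr, y_tr)
    return float(np.mean(clf.predict(X_te) == y_te))
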