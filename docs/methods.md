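# Methods

## Model

The package embeds an undirected (optionally weighted) graph by skip-gram
with negative sampling over truncated random-walk corpora, in two modes.

**Vanilla mode** is the classic recipe: `r` walks of length `t` from every
node (start order reshuffled each pass; the `uniform` strategy picks a
uniformly random neighbor, the `biased` strategy applies node2vec's
second-order return/in-out weights `1/p_ret, 1, 1/q`); a per-position
window radius drawn uniformly from `{1..m}` (the word2vec shrinking
window); and, per (center `u`, context `n`) pair, one positive update plus
`k` noise draws from the unigram distribution raised to the 0.75 power.

**Graph mode** multiplies each pair's co-occurrence score by a structure
closeness built from degrees `D` and shortest-path distances `P`:

    W(n, u) = w * clamp(D_u / D_n, [1, 1.1])
              + (1 - w) * max(0, 2 - 2 * P_un / p)^a
              [+ w' * weight(u, n)]                     (weighted graphs)

    A(n, u) = clip( sigmoid(f'(n) . f(u)) * W(n, u)^L , -1, 1 )

with reachability `L = 0` for identical or disconnected pairs and `L = 1`
otherwise, so unreachable pairs get a neutral multiplier of exactly 1.
The assumptions are the usual ones for this model family: conditional
independence of context draws given the center representation, symmetric
influence of the two nodes of a pair, and — specific to graph mode — that
closeness in degree hierarchy and in hop distance should raise the modeled
co-occurrence probability.

### Gradient

The update treats W as a constant multiplier of the co-occurrence
probability: the gradient scalar is `g = (label - A) * alpha`, and both row
updates (`f'(n) += f(u) * g * W^L`, error accumulator `+= f'(n) * g * W^L`,
applied to `f(u)` after the positive pair and its negatives) carry the same
`W^L` factor.  With all multipliers equal to 1, graph mode reproduces the
vanilla trajectory bit-for-bit — the suite asserts this exactly.  The
negative term uses the same A (hence the same W modulation); negatives
drawn far from the center therefore repel more weakly, which is the
intended reading of the objective.

Clipping bounds A to [-1, 1].  Since A = sigmoid * W >= 0, the lower bound
is unreachable; it is retained for fidelity to the model statement.  An
alternative reading that puts W *inside* the sigmoid is available as
`TrainConfig(w_inside_sigmoid=True)`; it is not the default because the
clipping rule only has content when A can exceed 1, which requires the
outside placement.

### Parameters

| parameter | meaning | default |
| --- | --- | --- |
| `w` | degree-vs-distance mixing weight, in (0, 1) | 0.8 |
| `p` | distance scale, > 1 | chosen as max observed distance + 1 |
| `a` | distance-term exponent, > 0 | 1.0 |
| `w'` | edge-weight coefficient (weighted graphs) | 0.0 |
| `d` | embedding dimension | 128 |
| `m` | window radius | 10 |
| `r`, `t` | walks per node, walk length | 80, 10 |
| `k` | negatives per positive | 5 |
| `alpha` | initial learning rate, linear decay to `alpha * 1e-4` | 0.025 |
| fusion ratio | fraction of nodes fused | 0.10 |

The small-network walkthrough (karate demo, acceptance script) instead uses
d=2, m=5, r=40, t=40, k=1 and w=0.8, p=5, a=1 — the regime in which the
2-d embedding geometry is inspectable directly.

Choosing `p` one above the largest observed finite distance keeps the
distance term strictly positive for every reachable pair; the base is
additionally clamped at 0 so fractional exponents (`a` = 0.5 or 0.1 are
useful when the distance distribution is highly concentrated) never see a
negative base.  When the distance distribution is unknown it is estimated
from single-source shortest paths out of a random sample of source nodes.

## Fusion (Fioepn)

After training, each node's input and output rows are scored for agreement;
the `floor(ratio * |V|)` lowest-scoring nodes (strict inequality against
the order-statistic threshold, so ratio 0 is the identity and ties at the
threshold are excluded) get the fused row `(f + f')/2`, everyone else keeps
`f`.  Two scores are implemented: cosine (default across the package —
scale-invariant across the two differently-initialized matrices) and the
raw dot product.  The karate demonstration protocol
(`experiments.karate_fusion_wgss_reduction`) defaults to the dot score: on
this network, dot-based selection is the variant whose fusion tightens the
small modularity classes, while cosine-based selection at ratio 0.5
spreads them.  Fusion is deliberately not idempotent (a second pass
re-averages); callers fuse once.

## Evaluation protocols

*Clustering*: classes come from greedy modularity maximization, numbered
1..K by decreasing size (ties broken by smallest member index) so that
"class 3" is well defined; on the karate graph this yields three classes.
Quality is measured by the Calinski–Harabasz index and the per-class
within-group sum of squares, both implemented directly from the textbook
formulas and cross-checked in the suite against an independent
implementation to 1e-10.

*Multi-label classification*: one-vs-rest logistic regression (L2,
C = 1.0) on a random train fraction, repeated; each test node receives its
top-k scored labels with k its true label count (a plain 0.5 threshold is
available); micro-F1 averaged over repeats.

*Link prediction*: edges are removed one at a time, rejecting removals that
would disconnect the residual graph, until the requested fraction is
reached; embeddings are retrained on the residual graph.  Training
positives are a residual-edge sample equal in size to the removed set; test
positives are the removed edges; negatives are sampled non-edges in equal
number — an overall 50/50 train/test split.  Edge features use the
symmetric operators average, Hadamard, |diff|, diff²; accuracy comes from
logistic regression on the training half.

## Synthetic data

The stochastic-block-model generator emulates the community structure of
interaction networks: dense within-block wiring at `p_in`, sparse
between-block wiring at `p_out`, planted labels attached to the graph.  The
recovery suite uses four blocks of 30 nodes with `p_in = 0.25`,
`p_out = 0.02` — strong but not trivial assortativity at a size where ten
replicate seeds run in seconds.  What the SBM does *not* emulate: the
heavy-tailed degree distributions, degree–community correlations, and
overlapping multi-label structure of real PPI or social graphs.  Passing
recovery tests therefore show that the pipeline separates planted
communities under clean assortative structure, not that it matches reported
performance on any real benchmark.

## Numerical choices

- Node identifiers are strings; a numeric-aware sort fixes row order, so
  integer-labeled files get the natural ordering reproducibly.
- Unreachable distances are stored as `inf` (never 0); the self-distance 0
  and `inf` both map to `L = 0`.  On weighted graphs, distances are
  weighted Dijkstra path lengths, and the `W` evaluated for an adjacent
  pair uses that weighted distance.
- Degree ratio is hard-clamped into [1, 1.1] (center degree over context
  degree).
- Input embeddings initialize i.i.d. uniform on [-0.5/d, 0.5/d]; output
  embeddings start at zero — the asymmetric init that accelerates early
  training because the two sets converge toward agreement anyway.
- Negative draws resample when they hit the center node; duplicates among
  the k draws are allowed.
- The dense |V| x |V| distance matrix is materialized below 20,000 nodes;
  above that, per-source rows are computed on demand and LRU-cached.
- The SGD inner loop is JIT-compiled (numba) with a pure-Python twin that
  executes identical floating-point operations; the suite asserts their
  outputs are bit-equal.  Training is single-threaded and bit-reproducible
  given the walk and train seeds; replicate seeds derive from one master
  seed via a seed sequence.
- Sigmoid saturates to 0/1 beyond |x| > 30 to avoid overflow; identical in
  both loop implementations.

## Known limitations

- Greedy modularity on the karate graph yields three classes, so per-class
  statistics are only comparable across partitions with the same class
  structure; partition-dependent quantities (e.g. a specific class's WGSS)
  are sensitive to this choice.
- Multi-threaded training is not implemented; the asynchronous lock-free
  variant common in word2vec implementations would forfeit reproducibility.
- No approximate shortest-path schemes beyond source sampling; very large
  graphs pay per-source Dijkstra cost on first access.
- The 2-d demo regime is for inspectability; representation quality
  claims at realistic dimensions (d = 128) are out of the demo's scope.
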