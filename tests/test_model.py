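"""Skip-gram training: initialization, noise distribution, the SGD update,
both training modes, and per-node sampling statistics."""

import numpy as np
import pytest
from scipy import stats

from graphskipgram.graph import EmbeddingSet, karate_fixture
from graphskipgram.model import (
    NoiseDistribution,
    TrainConfig,
    _sgd_loop,
    _sgd_loop_py,
    build_noise_distribution,
    co_occurrence_score,
    init_embeddings,
    log_score_gradient,
    pair_update,
    train,
)
from graphskipgram.structure import StructureInfo, StructureParams
from graphskipgram.walks import WalkConfig, WalkCorpus


KARATE_WALKS = dict(walks_per_node=40, walk_length=40, window=5)


class TestInit:
    def test_output_embedding_starts_at_zero(self):
        emb = init_embeddings(7, 4, seed=0)
        assert np.all(emb.f_out == 0.0)

    def test_input_range_bound(self):
        emb = init_embeddings(100, 8, seed=1)
        assert np.max(np.abs(emb.f)) <= 0.5 / 8

    def test_seed_determinism(self):
        a = init_embeddings(10, 3, seed=5)
        b = init_embeddings(10, 3, seed=5)
        c = init_embeddings(10, 3, seed=6)
        assert np.array_equal(a.f, b.f)
        assert not np.array_equal(a.f, c.f)


class TestNoiseDistribution:
    def test_exponent_zero_is_uniform_over_appearing_nodes(self):
        corpus = WalkCorpus(walks=[np.array([0, 0, 2])], n_nodes=4)
        noise = build_noise_distribution(corpus, exponent=0.0)
        assert noise.probs[1] == 0.0 and noise.probs[3] == 0.0
        assert noise.probs[0] == noise.probs[2] == 0.5

    def test_three_quarter_power_shrinks_frequency_gap(self):
        walks = [np.zeros(16, dtype=np.int64), np.array([1])]
        noise = build_noise_distribution(WalkCorpus(walks=walks, n_nodes=2), 0.75)
        assert noise.probs[0] == pytest.approx(8 / 9)
        assert noise.probs[1] == pytest.approx(1 / 9)

    def test_probabilities_sum_to_one(self, karate, rng):
        walks = [rng.integers(0, 34, size=20) for _ in range(10)]
        noise = build_noise_distribution(WalkCorpus(walks=walks, n_nodes=34))
        assert noise.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            NoiseDistribution(np.array([0.5, 0.4]))


class TestCoOccurrenceScore:
    def test_zero_vectors_with_multiplier(self):
        z = np.zeros(3)
        assert co_occurrence_score(z, z, W=1.2, L=1) == pytest.approx(0.6)

    def test_l_zero_deactivates_w(self, rng):
        a, b = rng.normal(size=3), rng.normal(size=3)
        plain = 1 / (1 + np.exp(-(a @ b)))
        assert co_occurrence_score(b, a, W=7.3, L=0) == pytest.approx(plain)

    def test_clipped_at_one(self):
        v = np.full(4, 10.0)
        assert co_occurrence_score(v, v, W=1.2, L=1) == 1.0


class TestPairUpdate:
    def test_zero_embeddings_positive_label(self):
        emb = EmbeddingSet(["a", "b"], np.zeros((2, 3)), np.zeros((2, 3)))
        acc = pair_update(0, 1, 1, emb, lr=0.1)
        # A = 0.5 so g = 0.05, but both vectors are zero: nothing moves
        assert np.all(acc == 0.0)
        assert np.all(emb.f_out == 0.0) and np.all(emb.f == 0.0)

    def test_neutral_multiplier_matches_vanilla(self, rng):
        f = rng.normal(size=(4, 3))
        fo = rng.normal(size=(4, 3))
        emb_a = EmbeddingSet(list("abcd"), f.copy(), fo.copy())
        emb_b = EmbeddingSet(list("abcd"), f.copy(), fo.copy())
        acc_a = pair_update(0, 2, 1, emb_a, lr=0.05, multiplier=1.0)
        acc_b = pair_update(0, 2, 1, emb_b, lr=0.05)
        assert np.array_equal(acc_a, acc_b)
        assert np.array_equal(emb_a.f_out, emb_b.f_out)

    @pytest.mark.parametrize("positive", [True, False])
    def test_gradient_matches_central_differences(self, positive, rng):
        """Analytic gradient of the log co-occurrence score agrees with
        central finite differences in the pre-clipping regime."""
        W, L = 1.1, 1
        for _ in range(10):
            f_u = rng.normal(scale=0.3, size=5)
            fo_n = rng.normal(scale=0.3, size=5)
            sign = 1.0 if positive else -1.0
            g_fu, g_fn = log_score_gradient(f_u, fo_n, positive=positive)
            eps = 1e-6
            for idx in range(5):
                for vec, grad in ((f_u, g_fu), (fo_n, g_fn)):
                    step = np.zeros(5)
                    step[idx] = eps
                    if vec is f_u:
                        hi = co_occurrence_score(f_u + step, sign * fo_n, W, L)
                        lo = co_occurrence_score(f_u - step, sign * fo_n, W, L)
                    else:
                        hi = co_occurrence_score(f_u, sign * (fo_n + step), W, L)
                        lo = co_occurrence_score(f_u, sign * (fo_n - step), W, L)
                    assert max(hi, lo) < 1.0, "clipping regime reached"
                    fd = (np.log(hi) - np.log(lo)) / (2 * eps)
                    assert abs(fd - grad[idx]) < 1e-5


class TestTrain:
    def test_zero_init_with_no_negatives_stays_zero(self):
        """Tracing the update by hand: with both matrices zero and k=0 the
        gradient scalar multiplies zero vectors, so nothing ever moves."""
        f = np.zeros((3, 2))
        fo = np.zeros((3, 2))
        _sgd_loop_py(
            f, fo,
            np.array([0]), np.array([1]),
            np.zeros((1, 0), dtype=np.int64),
            np.ones(1), np.ones((1, 0)), np.array([0.025]), False,
        )
        assert np.all(f == 0.0) and np.all(fo == 0.0)

    def test_jit_loop_matches_python_loop(self, rng):
        n, d, pairs, k = 8, 4, 200, 2
        args = dict(
            centers=rng.integers(n, size=pairs),
            contexts=rng.integers(n, size=pairs),
            negatives=rng.integers(n, size=(pairs, k)),
            mult_pos=rng.uniform(0.8, 1.2, size=pairs),
            mult_neg=rng.uniform(0.8, 1.2, size=(pairs, k)),
            lrs=np.full(pairs, 0.025),
        )
        f0 = rng.normal(scale=0.1, size=(n, d))
        fo0 = rng.normal(scale=0.1, size=(n, d))
        f1, fo1 = f0.copy(), fo0.copy()
        f2, fo2 = f0.copy(), fo0.copy()
        _sgd_loop_py(f1, fo1, inside=False, **args)
        _sgd_loop(f2, fo2, args["centers"], args["contexts"],
                  args["negatives"], args["mult_pos"], args["mult_neg"],
                  args["lrs"], False)
        assert np.array_equal(f1, f2) and np.array_equal(fo1, fo2)

    def test_graph_mode_requires_structure(self, karate):
        wcfg = WalkConfig(walks_per_node=1, walk_length=5, window=2, seed=0)
        tcfg = TrainConfig(dim=2, negatives=1, mode="graph", seed=0)
        with pytest.raises(ValueError, match="StructureInfo"):
            train(karate, wcfg, tcfg)

    def test_reduction_graph_mode_with_unit_multipliers(self, karate):
        """Graph mode with every structure multiplier forced to 1 reproduces
        the vanilla trajectory bit-for-bit under a shared seed."""
        wcfg = WalkConfig(walks_per_node=3, walk_length=15, window=3, seed=7)
        ones = np.ones((34, 34))
        emb_v = train(karate, wcfg, TrainConfig(dim=4, negatives=2, seed=7))
        emb_g = train(
            karate, wcfg,
            TrainConfig(dim=4, negatives=2, mode="graph", seed=7),
            structure_matrix=ones,
        )
        assert np.array_equal(emb_v.f, emb_g.f)
        assert np.array_equal(emb_v.f_out, emb_g.f_out)

    def test_single_thread_determinism(self, karate):
        wcfg = WalkConfig(walks_per_node=2, walk_length=10, window=3, seed=1)
        tcfg = TrainConfig(dim=3, negatives=1, seed=1)
        a = train(karate, wcfg, tcfg)
        b = train(karate, wcfg, tcfg)
        assert np.array_equal(a.f, b.f) and np.array_equal(a.f_out, b.f_out)

    def test_training_is_finite_and_contracts_positive_pairs(self, karate):
        """After training, positive (adjacent) pairs score above the 0.5
        they start from — the geometric contraction of the walk neighborhood."""
        wcfg = WalkConfig(seed=3, **KARATE_WALKS)
        emb = train(karate, wcfg, TrainConfig(dim=2, negatives=1, seed=3))
        assert np.all(np.isfinite(emb.f)) and np.all(np.isfinite(emb.f_out))
        sims = [
            1 / (1 + np.exp(-(emb.f_out[j] @ emb.f[i])))
            for i, j in karate.edges
        ]
        assert np.mean(sims) > 0.5

    @pytest.mark.parametrize("seed", [1, 4, 5])
    def test_hub_nodes_move_away_from_origin_early(self, karate, seed):
        """In the early training phase the hub nodes (highest degree) are
        driven far outside the initialization box, and their output rows end
        up farther from the origin than those of peripheral nodes — the
        sampling frequency of a node tracks its degree."""
        wcfg = WalkConfig(walks_per_node=5, walk_length=40, window=5, seed=seed)
        emb = train(karate, wcfg, TrainConfig(dim=2, negatives=1, seed=seed))
        deg = karate.degrees()
        hubs = deg >= 10
        f_norms = np.linalg.norm(emb.f, axis=1)
        fo_norms = np.linalg.norm(emb.f_out, axis=1)
        init_max = np.sqrt(2) * 0.25  # corner of the U[-0.25, 0.25]^2 box
        assert f_norms[hubs].mean() > 2 * init_max
        assert fo_norms[hubs].mean() > fo_norms[~hubs].mean()

    def test_graph_mode_runs_with_structure_info(self, karate):
        info = StructureInfo(karate, StructureParams(w=0.8, distance_scale_p=5))
        wcfg = WalkConfig(walks_per_node=2, walk_length=10, window=3, seed=2)
        emb = train(
            karate, wcfg,
            TrainConfig(dim=2, negatives=1, mode="graph", seed=2),
            info=info,
        )
        assert np.all(np.isfinite(emb.f))


class TestSamplingStats:
    def test_bookkeeping_identities(self, karate):
        wcfg = WalkConfig(walks_per_node=2, walk_length=10, window=3, seed=4)
        k = 3
        emb, st = train(
            karate, wcfg,
            TrainConfig(dim=2, negatives=k, seed=4),
            collect_stats=True,
        )
        assert st.pos_v.sum() == st.pos_c.sum()
        assert st.neg.sum() == k * st.pos_v.sum()

    def test_counts_track_degree_on_karate(self, karate):
        """Center, context, and negative-sample counts all correlate with
        node degree (Pearson r > 0.9) under the small-network settings."""
        wcfg = WalkConfig(seed=6, **KARATE_WALKS)
        _, st = train(
            karate, wcfg,
            TrainConfig(dim=2, negatives=1, seed=6),
            collect_stats=True,
        )
        deg = karate.degrees()
        for counts in (st.pos_v, st.pos_c, st.neg):
            assert stats.pearsonr(counts, deg).statistic > 0.9
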