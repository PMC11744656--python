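"""Link predictor: fusion attention, Transformer encoding, edge decoding,
negative sampling, BCE, training behaviour and permutation consistency."""

import math

import numpy as np
import pytest

from grnlink._autograd import Tensor
from grnlink.errors import ConfigError, StructuralError, UsageError
from grnlink.io import EdgeSet, EmbeddingTable
from grnlink.predictor import (
    LinkPredictionModel,
    LinkPredictionResults,
    PredictorConfig,
    _EncoderBlock,
    _Fusion,
    _LinkDecoder,
    bce_loss,
    encode_genes,
    fuse,
    sample_negatives,
    score_edges,
)
from grnlink.metrics import auroc
from grnlink.tcn import LatentTemporalFeatures


def _emb(genes, vectors):
    return EmbeddingTable(genes, np.asarray(vectors, dtype=float))


def _temporal(genes, features):
    return LatentTemporalFeatures(genes, np.asarray(features, dtype=float))


class TestFuse:
    def test_zero_attention_weights_give_uniform_alpha(self):
        genes = [f"G{i}" for i in range(5)]
        emb = _emb(genes, np.random.default_rng(0).normal(size=(5, 3)))
        temp = _temporal(genes, np.random.default_rng(1).normal(size=(5, 2)))
        fusion = _Fusion(5, 4, np.random.default_rng(2))
        fusion.attn.weight.data[:] = 0.0
        fusion.attn.bias.data[:] = 0.0
        out = fuse(emb, temp, fusion=fusion)
        np.testing.assert_allclose(out.alpha, np.full((5, 1), 0.2), atol=1e-12)

    def test_alpha_sums_to_one_for_any_params(self):
        genes = [f"G{i}" for i in range(7)]
        rng = np.random.default_rng(3)
        emb = _emb(genes, rng.normal(size=(7, 4)))
        temp = _temporal(genes, rng.normal(size=(7, 3)))
        out = fuse(emb, temp, seed=11)
        assert abs(out.alpha.sum() - 1.0) < 1e-9
        assert (out.alpha >= 0).all()
        assert out.h0.shape == (7, 7)

    def test_softmax_of_ln3_and_zero(self):
        # attention scores a = (ln 3, 0) -> alpha = (3/4, 1/4)
        genes = ["A", "B"]
        emb = _emb(genes, [[math.log(3.0)], [0.0]])
        temp = _temporal(genes, np.zeros((2, 1)))
        fusion = _Fusion(2, 2, np.random.default_rng(0))
        fusion.attn.weight.data[:] = [[1.0], [0.0]]
        fusion.attn.bias.data[:] = 0.0
        out = fuse(emb, temp, fusion=fusion)
        np.testing.assert_allclose(out.alpha.ravel(), [0.75, 0.25], atol=1e-12)
        # the per-gene scalar broadcasts across all feature columns
        np.testing.assert_allclose(out.h0_att, out.alpha * out.h0)

    def test_gene_order_mismatch_rejected(self):
        emb = _emb(["A", "B"], np.zeros((2, 2)))
        temp = _temporal(["B", "A"], np.zeros((2, 2)))
        with pytest.raises(UsageError):
            fuse(emb, temp)


class TestEncodeGenes:
    def test_eval_mode_is_deterministic(self):
        cfg = PredictorConfig(hidden_dim=8, n_heads=2, ff_dim=16, seed=0)
        h1 = np.random.default_rng(0).normal(size=(6, 8))
        block = _EncoderBlock(cfg, np.random.default_rng(1))
        out1 = encode_genes(h1, cfg, block=block)
        out2 = encode_genes(h1, cfg, block=block)
        np.testing.assert_array_equal(out1.h5, out2.h5)

    def test_permutation_equivariance(self):
        # no positional encoding: permuting gene rows permutes h5 rows identically
        cfg = PredictorConfig(hidden_dim=8, n_heads=2, ff_dim=16, seed=0)
        h1 = np.random.default_rng(2).normal(size=(6, 8))
        block = _EncoderBlock(cfg, np.random.default_rng(3))
        perm = np.random.default_rng(4).permutation(6)
        out = encode_genes(h1, cfg, block=block).h5
        out_p = encode_genes(h1[perm], cfg, block=block).h5
        np.testing.assert_allclose(out_p, out[perm], atol=1e-12)

    def test_rows_are_layernormed_at_identity_affine(self):
        cfg = PredictorConfig(hidden_dim=16, n_heads=4, ff_dim=8, seed=0)
        h1 = np.random.default_rng(5).normal(size=(4, 16))
        h5 = encode_genes(h1, cfg, seed=9).h5
        np.testing.assert_allclose(h5.mean(axis=1), 0.0, atol=1e-8)
        np.testing.assert_allclose(h5.var(axis=1), 1.0, atol=1e-3)

    def test_hidden_dim_not_divisible_by_heads_is_config_error(self):
        with pytest.raises(ConfigError):
            PredictorConfig(hidden_dim=10, n_heads=4)


class TestScoreEdges:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.genes = [f"G{i}" for i in range(4)]
        self.h5 = rng.normal(size=(4, 6))

    def test_zero_decoder_scores_half(self):
        dec = _LinkDecoder(6, np.random.default_rng(1))
        dec.fc.weight.data[:] = 0.0
        dec.fc.bias.data[:] = 0.0
        table = score_edges(self.h5, [("G0", "G1"), ("G2", "G3")],
                            gene_names=self.genes, decoder=dec)
        np.testing.assert_array_equal(table.scores, [0.5, 0.5])

    def test_direction_sensitivity(self):
        table = score_edges(self.h5, [("G0", "G1"), ("G1", "G0")],
                            gene_names=self.genes, seed=5)
        assert table.scores[0] != table.scores[1]

    def test_bias_ln3_gives_three_quarters(self):
        dec = _LinkDecoder(6, np.random.default_rng(1))
        dec.fc.weight.data[:] = 0.0
        dec.fc.bias.data[:] = math.log(3.0)
        table = score_edges(self.h5, [("G0", "G2")], gene_names=self.genes,
                            decoder=dec)
        np.testing.assert_allclose(table.scores, [0.75], atol=1e-12)

    def test_unknown_gene_listed_in_error(self):
        with pytest.raises(UsageError, match="XX"):
            score_edges(self.h5, [("G0", "XX")], gene_names=self.genes)


class TestBceLoss:
    def test_perfect_predictions_give_near_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        assert bce_loss(y, y) < 1e-6

    def test_single_pair_half_score_is_ln2(self):
        assert bce_loss([0.5], [1]) == pytest.approx(math.log(2), abs=1e-12)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(6)
        s = rng.uniform(0.01, 0.99, 7)
        y = rng.integers(0, 2, 7)
        expected = -sum(
            yi * math.log(si) + (1 - yi) * math.log(1 - si)
            for si, yi in zip(s, y)
        ) / 7
        assert bce_loss(s, y) == pytest.approx(expected, rel=1e-12)

    def test_clipping_keeps_loss_finite(self):
        assert np.isfinite(bce_loss([0.0, 1.0], [1, 0]))

    def test_empty_input_rejected(self):
        with pytest.raises(UsageError):
            bce_loss([], [])


class TestSampleNegatives:
    def test_count_and_disjointness(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(15)]
        pos = EdgeSet([(genes[i % 3], genes[3 + i], 1) for i in range(10)])
        neg = sample_negatives(pos, genes, ratio=1.0, seed=4)
        assert len(neg) == 10
        assert all(lab == 0 for _, _, lab in neg.edges)
        assert not set(neg.pairs) & set(pos.pairs)
        assert all(r in pos.regulator_universe for r, _ in neg.pairs)

    def test_same_seed_identical(self):
        genes = [f"G{i}" for i in range(10)]
        pos = EdgeSet([("G0", "G5", 1), ("G1", "G6", 1)])
        n1 = sample_negatives(pos, genes, seed=3)
        n2 = sample_negatives(pos, genes, seed=3)
        assert n1.edges == n2.edges

    def test_exhausted_candidate_set_is_structural_error(self):
        # 3 genes, single regulator A with both its non-self targets positive:
        # brute-force candidate set {(A,B),(A,C)} minus positives is empty
        pos = EdgeSet([("A", "B", 1), ("A", "C", 1)])
        with pytest.raises(StructuralError):
            sample_negatives(pos, ["A", "B", "C"], ratio=1.0, seed=0)

    def test_ceil_of_fractional_ratio(self):
        genes = [f"G{i}" for i in range(10)]
        pos = EdgeSet([("G0", f"G{i}", 1) for i in range(1, 4)])
        assert len(sample_negatives(pos, genes, ratio=0.5, seed=0)) == 2


def _toy_model_inputs(n_genes=12, seed=0, emb_dim=6, temp_dim=3):
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(n_genes)]
    emb = _emb(genes, rng.normal(size=(n_genes, emb_dim)))
    temp = _temporal(genes, rng.normal(size=(n_genes, temp_dim)))
    return genes, emb, temp


_FAST = dict(hidden_dim=16, n_heads=2, ff_dim=32)


class TestTraining:
    def test_requires_both_labels(self):
        genes, emb, temp = _toy_model_inputs()
        model = LinkPredictionModel(emb, temp, PredictorConfig(**_FAST))
        with pytest.raises(UsageError, match="both"):
            model.fit(EdgeSet([("G0", "G1", 1), ("G0", "G2", 1)]))

    def test_seeded_training_reproducible(self, labeled_edges):
        genes, emb, temp = _toy_model_inputs(6)
        cfg = PredictorConfig(epochs=20, seed=5, **_FAST)
        c1 = LinkPredictionModel(emb, temp, cfg).fit(labeled_edges).loss_curve
        c2 = LinkPredictionModel(emb, temp, cfg).fit(labeled_edges).loss_curve
        np.testing.assert_array_equal(c1, c2)

    def test_loss_decreases_on_informative_toy(self, labeled_edges):
        genes, emb, temp = _toy_model_inputs(6)
        res = LinkPredictionModel(
            emb, temp, PredictorConfig(epochs=60, seed=1, **_FAST)
        ).fit(labeled_edges)
        assert res.loss_curve[-1] < res.loss_curve[0]

    def test_linearly_separable_features_reach_perfect_training_auroc(self):
        # positive targets at [0, +1, ...], negative targets at [0, -1, ...]
        genes = ["R0", "R1"] + [f"T{i}" for i in range(8)]
        vec = {g: np.zeros(4) for g in genes}
        for g in ("R0", "R1"):
            vec[g][0] = 1.0
        for i in range(8):
            vec[f"T{i}"][1] = 1.0 if i < 4 else -1.0
        emb = _emb(genes, [vec[g] for g in genes])
        temp = _temporal(genes, np.zeros((10, 1)))
        edges = EdgeSet(
            [("R0", f"T{i}", 1) for i in range(4)]
            + [("R1", f"T{i}", 0) for i in range(4, 8)]
        )
        res = LinkPredictionModel(
            emb, temp, PredictorConfig(epochs=300, seed=2, dropout_p=0.0, **_FAST)
        ).fit(edges)
        scores = res.predict(edges.pairs).scores
        assert auroc(scores, edges.labels) == 1.0

    def test_positive_scores_exceed_negative_scores_after_convergence(
            self, labeled_edges):
        genes, emb, temp = _toy_model_inputs(6)
        res = LinkPredictionModel(
            emb, temp, PredictorConfig(epochs=200, seed=3, dropout_p=0.0, **_FAST)
        ).fit(labeled_edges)
        table = res.predict(labeled_edges.pairs)
        labs = labeled_edges.labels
        assert table.scores[labs == 1].mean() > table.scores[labs == 0].mean()


class TestPredict:
    @pytest.fixture
    def fitted(self, labeled_edges):
        genes, emb, temp = _toy_model_inputs(10)
        cfg = PredictorConfig(epochs=15, seed=0, **_FAST)
        return LinkPredictionModel(emb, temp, cfg).fit(labeled_edges)

    def test_scores_in_unit_interval_and_deterministic(self, fitted):
        pairs = [("G7", "G8"), ("G0", "G9")]
        t1 = fitted.predict(pairs)
        t2 = fitted.predict(pairs)
        np.testing.assert_array_equal(t1.scores, t2.scores)
        assert ((t1.scores >= 0) & (t1.scores <= 1)).all()

    def test_all_pairs_combinatorics(self, fitted):
        table = fitted.predict_all_pairs(regulators=["G0", "G1", "G2"])
        assert len(table) == 3 * 9  # self-pairs excluded

    def test_unseen_regulator_is_scored_not_rejected(self, fitted):
        # G7 never appears in any training edge but has features
        table = fitted.predict([("G7", "G2")])
        assert 0.0 <= table.scores[0] <= 1.0

    def test_unknown_gene_rejected_with_offenders(self, fitted):
        with pytest.raises(UsageError, match="ZZ"):
            fitted.predict([("G0", "ZZ")])

    def test_checkpoint_round_trip(self, fitted, tmp_path):
        fitted.save(tmp_path / "ckpt.npz")
        back = LinkPredictionResults.load(tmp_path / "ckpt.npz")
        pairs = [("G3", "G5"), ("G1", "G4")]
        np.testing.assert_allclose(back.predict(pairs).scores,
                                   fitted.predict(pairs).scores, atol=1e-12)


class TestInvariants:
    def test_gene_relabeling_leaves_scores_unchanged(self, labeled_edges):
        genes, emb, temp = _toy_model_inputs(6)
        cfg = PredictorConfig(epochs=25, seed=4, dropout_p=0.0, **_FAST)
        res = LinkPredictionModel(emb, temp, cfg).fit(labeled_edges)
        perm = np.random.default_rng(8).permutation(6)
        emb_p = _emb([genes[i] for i in perm], emb.vectors[perm])
        temp_p = _temporal([genes[i] for i in perm], temp.features[perm])
        res_p = LinkPredictionModel(emb_p, temp_p, cfg).fit(labeled_edges)
        pairs = labeled_edges.pairs
        np.testing.assert_allclose(res_p.predict(pairs).scores,
                                   res.predict(pairs).scores, atol=1e-9)

    def test_zeroing_temporal_never_improves_training_loss(self, small_benchmark):
        # planted signal is partly temporal: ablation checked over 5 seeds
        dataset, _ = small_benchmark
        from grnlink.tcn import TCNAutoencoder, TCNConfig
        temporal = TCNAutoencoder(
            dataset.trajectory,
            TCNConfig(n_blocks=2, channel_schedule=[4, 8], latent_dim=8,
                      epochs=25, seed=0),
        ).fit().encode()
        diffs = []
        for seed in range(5):
            pos = dataset.edges.positives()
            neg = sample_negatives(pos, dataset.gene_names, seed=seed)
            train = EdgeSet(pos.edges + neg.edges,
                            regulator_universe=pos.regulator_universe)
            res = LinkPredictionModel(
                dataset.embeddings, temporal,
                PredictorConfig(epochs=80, seed=seed, **_FAST),
            ).fit(train)
            diffs.append(res.training_loss(zero_temporal=True)
                         - res.training_loss(zero_temporal=False))
        assert np.mean(diffs) > -1e-3
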