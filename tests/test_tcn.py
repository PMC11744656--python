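"""Temporal-convolutional autoencoder: block semantics, encoding contracts,
training behaviour and the causality property."""

import numpy as np
import pytest

from grnlink.errors import ConfigError, UsageError
from grnlink.io import ExpressionTrajectory
from grnlink.tcn import (
    LatentTemporalFeatures,
    TCNAutoencoder,
    TCNConfig,
    TemporalBlock,
    TemporalBlockConfig,
    mse_loss,
    temporal_block_forward,
)


def _zeroed(block: TemporalBlock) -> TemporalBlock:
    state = {k: np.zeros_like(v) for k, v in block.state_dict().items()}
    return block.load_state_dict(state)


class TestTemporalBlock:
    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            TemporalBlockConfig(1, 1, kernel_size=0)
        with pytest.raises(ConfigError):
            TemporalBlockConfig(1, 1, dilation=0)

    def test_zero_weights_zero_input_give_zero_output(self):
        cfg = TemporalBlockConfig(1, 4, kernel_size=3, dilation=2)
        block = _zeroed(TemporalBlock(cfg, np.random.default_rng(0)))
        out = temporal_block_forward(np.zeros((1, 10)), cfg, block=block)
        np.testing.assert_array_equal(out, np.zeros((4, 10)))

    @pytest.mark.parametrize("kernel,dilation,length", [
        (3, 4, 16), (2, 1, 5), (5, 2, 33), (1, 1, 7),
    ])
    def test_length_preserved(self, kernel, dilation, length):
        cfg = TemporalBlockConfig(2, 3, kernel_size=kernel, dilation=dilation)
        out = temporal_block_forward(np.random.default_rng(1).random((2, length)), cfg)
        assert out.shape == (3, length)

    def test_identity_kernel_gives_relu_of_twice_input(self):
        # 1 channel in/out, conv weights = causal identity tap, biases 0:
        # each sublayer passes the (non-negative) input through unchanged and
        # the residual doubles it.  Hand-computable on a length-4 sequence.
        cfg = TemporalBlockConfig(1, 1, kernel_size=3, dilation=1, dropout_p=0.0)
        block = TemporalBlock(cfg, np.random.default_rng(0))
        state = {k: np.zeros_like(v) for k, v in block.state_dict().items()}
        for key in ("conv1.weight", "conv2.weight"):
            w = state[key]
            w[0, 0, -1] = 1.0  # most recent time step -> identity under causal pad
        block.load_state_dict(state)
        x = np.array([[0.0, 1.0, 2.0, 0.5]])
        out = temporal_block_forward(x, cfg, mode="eval", block=block)
        np.testing.assert_allclose(out, 2.0 * x)  # ReLU(x + x) for x >= 0

    def test_eval_mode_dropout_is_identity(self):
        cfg = TemporalBlockConfig(1, 2, kernel_size=3, dilation=1, dropout_p=0.9)
        block = TemporalBlock(cfg, np.random.default_rng(2))
        x = np.random.default_rng(3).random((1, 12))
        out1 = temporal_block_forward(x, cfg, mode="eval", block=block)
        out2 = temporal_block_forward(x, cfg, mode="eval", block=block)
        np.testing.assert_array_equal(out1, out2)


class TestMseLoss:
    def test_identity_is_zero(self):
        x = np.random.default_rng(0).random((3, 5))
        assert mse_loss(x, x) == 0.0

    def test_printed_formula_normalizes_by_gene_count_only(self):
        x = np.zeros((2, 2))
        xh = np.ones((2, 2))
        assert mse_loss(x, xh) == pytest.approx(4 / 2)  # sum of sq errors / C

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(4)
        x, xh = rng.random((3, 5)), rng.random((3, 5))
        expected = sum((x[j, k] - xh[j, k]) ** 2
                       for j in range(3) for k in range(5)) / 3
        assert mse_loss(x, xh) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(UsageError):
            mse_loss(np.zeros((2, 2)), np.zeros((2, 3)))


@pytest.fixture
def tiny_cfg():
    return TCNConfig(n_blocks=2, channel_schedule=[4, 6], latent_dim=6,
                     kernel_size=3, epochs=5, seed=0)


class TestAutoencoder:
    def test_config_validation(self):
        with pytest.raises(ConfigError):
            TCNConfig(n_blocks=2, channel_schedule=[4], latent_dim=4)
        with pytest.raises(ConfigError):
            TCNConfig(channel_schedule=[16, 32, 32], latent_dim=8)

    def test_encode_shape_and_determinism(self, smooth_trajectory, tiny_cfg):
        res = TCNAutoencoder(smooth_trajectory, tiny_cfg).fit()
        feats = res.encode()
        assert isinstance(feats, LatentTemporalFeatures)
        assert feats.features.shape == (8, 6)
        np.testing.assert_array_equal(feats.features, res.encode().features)

    def test_identical_profiles_get_identical_features(self, tiny_cfg):
        x = np.random.default_rng(0).random(20)
        values = np.vstack([x, x, x * 2])
        traj = ExpressionTrajectory(["A", "B", "C"], [f"c{i}" for i in range(20)],
                                    values)
        feats = TCNAutoencoder(traj, tiny_cfg).fit().encode()
        np.testing.assert_array_equal(feats.features[0], feats.features[1])

    def test_zero_gene_zero_bias_network_gives_zero_feature_row(
            self, smooth_trajectory, tiny_cfg):
        values = smooth_trajectory.values.copy()
        values[3] = 0.0
        traj = ExpressionTrajectory(smooth_trajectory.gene_names,
                                    smooth_trajectory.cell_names, values)
        res = TCNAutoencoder(traj, tiny_cfg).fit()
        state = res.encoder.state_dict()
        res.encoder.load_state_dict(
            {k: (np.zeros_like(v) if k.endswith("bias") else v)
             for k, v in state.items()})
        feats = res.encode()
        np.testing.assert_array_equal(feats.features[3], np.zeros(6))

    def test_unfitted_model_encode_is_usage_error(self, smooth_trajectory, tiny_cfg):
        with pytest.raises(UsageError, match="fit"):
            TCNAutoencoder(smooth_trajectory, tiny_cfg).encode()

    def test_reconstruct_shape_and_finite_mse(self, smooth_trajectory, tiny_cfg):
        res = TCNAutoencoder(smooth_trajectory, tiny_cfg).fit()
        xhat = res.reconstruct()
        assert xhat.shape == smooth_trajectory.values.shape
        assert np.isfinite(res.reconstruction_mse())
        assert res.reconstruction_mse() >= 0

    def test_training_beats_mean_predictor_on_rank1_input(self):
        t = np.linspace(0, 1, 40)
        profile = np.sin(2 * np.pi * t) + 1.5
        loadings = np.linspace(0.5, 2.0, 10)
        values = np.outer(loadings, profile)  # rank-1, noiseless
        traj = ExpressionTrajectory([f"G{i}" for i in range(10)],
                                    [f"c{j}" for j in range(40)], values)
        cfg = TCNConfig(n_blocks=2, channel_schedule=[8, 8], latent_dim=8,
                        epochs=150, seed=0)
        res = TCNAutoencoder(traj, cfg).fit()
        baseline = ((values - values.mean(axis=1, keepdims=True)) ** 2).sum() / 10
        assert res.reconstruction_mse() < baseline

    def test_seeded_training_is_bit_reproducible(self, smooth_trajectory, tiny_cfg):
        c1 = TCNAutoencoder(smooth_trajectory, tiny_cfg).fit().loss_curve
        c2 = TCNAutoencoder(smooth_trajectory, tiny_cfg).fit().loss_curve
        np.testing.assert_array_equal(c1, c2)

    def test_zero_epochs_returns_initialized_state_and_empty_curve(
            self, smooth_trajectory):
        cfg = TCNConfig(n_blocks=2, channel_schedule=[4, 4], latent_dim=4,
                        epochs=0, seed=1)
        res = TCNAutoencoder(smooth_trajectory, cfg).fit()
        assert len(res.loss_curve) == 0
        assert res.encode().features.shape == (8, 4)

    def test_checkpoint_round_trip(self, smooth_trajectory, tiny_cfg, tmp_path):
        res = TCNAutoencoder(smooth_trajectory, tiny_cfg).fit()
        res.save(tmp_path / "ckpt.npz")
        from grnlink.tcn import TCNAutoencoderResults
        back = TCNAutoencoderResults.load(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(back.encode(smooth_trajectory).features,
                                      res.encode().features)


class TestCausality:
    def test_perturbation_only_propagates_forward(self, smooth_trajectory):
        cfg = TCNConfig(n_blocks=3, channel_schedule=[4, 4, 4], latent_dim=4,
                        epochs=0, seed=2)
        res = TCNAutoencoder(smooth_trajectory, cfg).fit()
        z0 = res.latent_sequence()
        perturbed = smooth_trajectory.values.copy()
        t = 11
        perturbed[:, t] += 5.0
        traj_p = ExpressionTrajectory(smooth_trajectory.gene_names,
                                      smooth_trajectory.cell_names, perturbed)
        z1 = res.latent_sequence(traj_p)
        np.testing.assert_array_equal(z0[:, :, :t], z1[:, :, :t])
        assert np.any(z0[:, :, t:] != z1[:, :, t:])
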