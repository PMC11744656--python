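"""Temporal-convolutional autoencoder over pseudotime expression profiles.

Each gene's expression along the trajectory is a single-channel sequence of
length L (cells in pseudotime order).  A stack of dilated causal temporal
blocks (conv -> chomp -> ReLU -> dropout, twice, plus a residual connection
with a 1x1 downsample when channel counts change) encodes the sequence into a
latent C' x L representation; a mirrored decoder reconstructs the input and
the whole stack is trained with a reconstruction MSE normalised by gene count.
The per-gene temporal feature vector handed to the link predictor is the
latent sequence mean-pooled over the temporal axis (an F' = C' vector per
gene).

The causal structure guarantees that the latent value at trajectory position
t depends only on expression at positions <= t; this is asserted as a
property test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autograd import Adam, Tensor
from ._nn import Conv1dCausal, Dropout, Module
from .errors import ConfigError, TrainingError, UsageError
from .io import ExpressionTrajectory

__all__ = [
    "TemporalBlockConfig",
    "TCNConfig",
    "LatentTemporalFeatures",
    "TemporalBlock",
    "TCNAutoencoder",
    "TCNAutoencoderResults",
    "temporal_block_forward",
    "train_autoencoder",
    "encode",
    "reconstruct",
    "mse_loss",
]


@dataclass
class TemporalBlockConfig:
    in_channels: int
    out_channels: int
    kernel_size: int = 3
    dilation: int = 1
    dropout_p: float = 0.1

    def __post_init__(self):
        if self.kernel_size < 1:
            raise ConfigError(f"kernel_size must be >= 1, got {self.kernel_size}")
        if self.dilation < 1:
            raise ConfigError(f"dilation must be >= 1, got {self.dilation}")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ConfigError(f"dropout_p must be in [0, 1), got {self.dropout_p}")


@dataclass
class TCNConfig:
    """Autoencoder architecture and training hyperparameters.

    ``channel_schedule[-1]`` is the latent channel count C', which equals the
    temporal feature dimension F' after mean pooling.
    """

    n_blocks: int = 3
    channel_schedule: list[int] = field(default_factory=lambda: [16, 32, 32])
    kernel_size: int = 3
    dilation_schedule: list[int] | None = None  # default 2^i
    dropout_p: float = 0.1
    latent_dim: int = 32
    epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.dilation_schedule is None:
            self.dilation_schedule = [2**i for i in range(self.n_blocks)]
        if len(self.channel_schedule) != self.n_blocks:
            raise ConfigError("channel_schedule length must equal n_blocks")
        if len(self.dilation_schedule) != self.n_blocks:
            raise ConfigError("dilation_schedule length must equal n_blocks")
        if any(d < 1 for d in self.dilation_schedule):
            raise ConfigError("dilations must be >= 1")
        if self.channel_schedule[-1] != self.latent_dim:
            raise ConfigError(
                "latent_dim must equal the last entry of channel_schedule "
                f"({self.channel_schedule[-1]} != {self.latent_dim})"
            )


@dataclass
class LatentTemporalFeatures:
    """Per-gene temporal feature vectors (genes x F')."""

    gene_names: list[str]
    features: np.ndarray

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.shape[0] != len(self.gene_names):
            raise UsageError("feature row count differs from gene count")
        if not np.all(np.isfinite(self.features)):
            raise UsageError("temporal features contain non-finite values")

    @property
    def dim(self) -> int:
        return self.features.shape[1]


class TemporalBlock(Module):
    """Two dilated causal conv sublayers plus a residual connection.

    Each sublayer is conv -> (implicit chomp) -> ReLU -> dropout; the block
    output is ``ReLU(Y2 + residual(X))`` where the residual path applies a 1x1
    convolution when in/out channel counts differ.
    """

    def __init__(self, cfg: TemporalBlockConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.conv1 = Conv1dCausal(cfg.in_channels, cfg.out_channels,
                                  cfg.kernel_size, cfg.dilation, rng)
        self.drop1 = Dropout(cfg.dropout_p, rng)
        self.conv2 = Conv1dCausal(cfg.out_channels, cfg.out_channels,
                                  cfg.kernel_size, cfg.dilation, rng)
        self.drop2 = Dropout(cfg.dropout_p, rng)
        self.downsample = (
            Conv1dCausal(cfg.in_channels, cfg.out_channels, 1, 1, rng)
            if cfg.in_channels != cfg.out_channels else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        y1 = self.drop1(self.conv1(x).relu())
        y2 = self.drop2(self.conv2(y1).relu())
        res = self.downsample(x) if self.downsample is not None else x
        return (y2 + res).relu()


def temporal_block_forward(x: np.ndarray, cfg: TemporalBlockConfig,
                           mode: str = "eval", block: TemporalBlock | None = None,
                           seed: int = 0) -> np.ndarray:
    """Run one temporal block on ``x`` (``(channels, L)`` or ``(B, channels, L)``).

    A fresh seeded block is built unless ``block`` (e.g. with hand-set
    weights) is supplied.  ``mode='eval'`` makes dropout the identity.
    """
    if block is None:
        block = TemporalBlock(cfg, np.random.default_rng(seed))
    block.eval() if mode == "eval" else block.train()
    arr = np.asarray(x, dtype=np.float64)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    out = block(Tensor(arr)).data
    return out[0] if squeeze else out


class _Encoder(Module):
    def __init__(self, cfg: TCNConfig, rng: np.random.Generator):
        super().__init__()
        ins = [1] + cfg.channel_schedule[:-1]
        self.blocks = [
            TemporalBlock(
                TemporalBlockConfig(i, o, cfg.kernel_size, d, cfg.dropout_p), rng
            )
            for i, o, d in zip(ins, cfg.channel_schedule, cfg.dilation_schedule)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


class _Decoder(Module):
    """Mirror of the encoder block structure plus a final 1x1 projection to
    one output channel."""

    def __init__(self, cfg: TCNConfig, rng: np.random.Generator):
        super().__init__()
        outs = list(reversed(cfg.channel_schedule))
        ins = [cfg.latent_dim] + outs[:-1]
        dils = list(reversed(cfg.dilation_schedule))
        self.blocks = [
            TemporalBlock(
                TemporalBlockConfig(i, o, cfg.kernel_size, d, cfg.dropout_p), rng
            )
            for i, o, d in zip(ins, outs, dils)
        ]
        self.proj = Conv1dCausal(outs[-1], 1, 1, 1, rng)

    def __call__(self, z: Tensor) -> Tensor:
        for b in self.blocks:
            z = b(z)
        return self.proj(z)


def mse_loss(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Reconstruction loss: squared error summed over all entries, normalised
    by the gene count C only (not C*L)."""
    X = np.asarray(X, dtype=np.float64)
    X_hat = np.asarray(X_hat, dtype=np.float64)
    if X.shape != X_hat.shape:
        raise UsageError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    C = X.shape[0]
    return float(((X - X_hat) ** 2).sum() / C)


class TCNAutoencoder:
    """Autoencoder model over an :class:`~grnlink.io.ExpressionTrajectory`.

    statsmodels-style usage::

        res = TCNAutoencoder(trajectory, TCNConfig(seed=0)).fit()
        temporal = res.encode()          # genes x F' LatentTemporalFeatures
        print(res.summary())
    """

    def __init__(self, trajectory: ExpressionTrajectory, config: TCNConfig | None = None):
        if trajectory.n_genes == 0 or trajectory.n_cells == 0:
            raise UsageError("cannot fit an autoencoder on an empty trajectory")
        self.trajectory = trajectory
        self.config = config or TCNConfig()
        self._results: TCNAutoencoderResults | None = None

    def fit(self) -> "TCNAutoencoderResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        encoder = _Encoder(cfg, rng)
        decoder = _Decoder(cfg, rng)
        X = self.trajectory.ordered_values()[:, None, :]  # (C, 1, L)
        C = X.shape[0]
        params = encoder.parameters() + decoder.parameters()
        opt = Adam(params, lr=cfg.learning_rate)
        curve: list[float] = []
        encoder.train()
        decoder.train()
        xin = Tensor(X)
        for epoch in range(cfg.epochs):
            opt.zero_grad()
            xhat = decoder(encoder(xin))
            diff = xhat - xin
            loss = (diff * diff).sum() * (1.0 / C)
            value = float(loss.data)
            if not np.isfinite(value):
                raise TrainingError(f"non-finite reconstruction loss at epoch {epoch}")
            loss.backward()
            opt.step()
            curve.append(value)
        encoder.eval()
        decoder.eval()
        self._results = TCNAutoencoderResults(
            encoder=encoder, decoder=decoder, config=cfg,
            gene_names=list(self.trajectory.gene_names),
            loss_curve=np.array(curve),
            trajectory=self.trajectory,
        )
        return self._results

    def encode(self) -> LatentTemporalFeatures:
        if self._results is None:
            raise UsageError("model has not been fitted; call fit() first")
        return self._results.encode()


class TCNAutoencoderResults:
    """Trained autoencoder state: encoder/decoder weights, config, loss curve."""

    def __init__(self, encoder: _Encoder, decoder: _Decoder, config: TCNConfig,
                 gene_names: list[str], loss_curve: np.ndarray,
                 trajectory: ExpressionTrajectory | None = None):
        self.encoder = encoder
        self.decoder = decoder
        self.config = config
        self.gene_names = gene_names
        self.loss_curve = loss_curve
        self.trajectory = trajectory

    def _prepare(self, trajectory: ExpressionTrajectory | None) -> ExpressionTrajectory:
        traj = trajectory if trajectory is not None else self.trajectory
        if traj is None:
            raise UsageError("no trajectory supplied")
        return traj

    def latent_sequence(self, trajectory: ExpressionTrajectory | None = None) -> np.ndarray:
        """Latent representation Z, shape (genes, C', L), eval mode."""
        traj = self._prepare(trajectory)
        self.encoder.eval()
        X = traj.ordered_values()[:, None, :]
        return self.encoder(Tensor(X)).data

    def encode(self, trajectory: ExpressionTrajectory | None = None) -> LatentTemporalFeatures:
        """Mean-pool the latent sequence over the temporal axis -> genes x F'."""
        traj = self._prepare(trajectory)
        z = self.latent_sequence(traj)
        return LatentTemporalFeatures(list(traj.gene_names), z.mean(axis=2))

    def reconstruct(self, trajectory: ExpressionTrajectory | None = None) -> np.ndarray:
        """Decoder output, same shape (genes x cells, pseudotime order) as input."""
        traj = self._prepare(trajectory)
        self.encoder.eval()
        self.decoder.eval()
        X = traj.ordered_values()[:, None, :]
        return self.decoder(self.encoder(Tensor(X))).data[:, 0, :]

    def reconstruction_mse(self, trajectory: ExpressionTrajectory | None = None) -> float:
        traj = self._prepare(trajectory)
        return mse_loss(traj.ordered_values(), self.reconstruct(traj))

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "TCN autoencoder results",
            "=" * 40,
            f"genes:            {len(self.gene_names)}",
            f"blocks:           {cfg.n_blocks} (channels {cfg.channel_schedule}, "
            f"dilations {cfg.dilation_schedule})",
            f"latent dim (F'):  {cfg.latent_dim}",
            f"epochs trained:   {len(self.loss_curve)}",
        ]
        if len(self.loss_curve):
            lines.append(f"first-epoch loss: {self.loss_curve[0]:.6g}")
            lines.append(f"final loss:       {self.loss_curve[-1]:.6g}")
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------------
    def save(self, path):
        state = {f"enc.{k}": v for k, v in self.encoder.state_dict().items()}
        state.update({f"dec.{k}": v for k, v in self.decoder.state_dict().items()})
        meta = json.dumps({"config": asdict(self.config), "gene_names": self.gene_names})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 __loss_curve__=self.loss_curve, **state)

    @classmethod
    def load(cls, path) -> "TCNAutoencoderResults":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = TCNConfig(**meta["config"])
        rng = np.random.default_rng(cfg.seed)
        encoder = _Encoder(cfg, rng)
        decoder = _Decoder(cfg, rng)
        encoder.load_state_dict(
            {k[4:]: data[k] for k in data.files if k.startswith("enc.")})
        decoder.load_state_dict(
            {k[4:]: data[k] for k in data.files if k.startswith("dec.")})
        encoder.eval()
        decoder.eval()
        return cls(encoder, decoder, cfg, meta["gene_names"], data["__loss_curve__"])


# -- functional wrappers matching the operation-level API ----------------------

def train_autoencoder(trajectory: ExpressionTrajectory,
                      cfg: TCNConfig | None = None) -> TCNAutoencoderResults:
    return TCNAutoencoder(trajectory, cfg).fit()


def encode(trajectory: ExpressionTrajectory,
           results: TCNAutoencoderResults) -> LatentTemporalFeatures:
    return results.encode(trajectory)


def reconstruct(trajectory: ExpressionTrajectory,
                results: TCNAutoencoderResults) -> np.ndarray:
    return results.reconstruct(trajectory)
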