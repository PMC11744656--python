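"""Standard planted-benchmark study: shared configurations and one-call runs.

This module fixes, in one place, the problem sizes used for protocol-level
evaluation on the default 50-gene / 5-TF / 200-cell benchmark: a compact
autoencoder (16 latent channels, 40 epochs) and a predictor trained for 300
full-batch epochs.  With only a handful of labeled edges per training shard,
one epoch is a single gradient step, so the benchmark predictor trains for
more epochs than the mini-batch module default; the autoencoder is sized so
a full multi-seed protocol comparison runs in minutes on one CPU.

The same configurations back the test suite and the reproduction script, so
every reported number comes from one definition of the study conditions.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .io import AlignedDataset
from .predictor import PredictorConfig
from .protocols import ProtocolResults, SplitPlan, make_split, run_protocol
from .simulate import EmbeddingFixtureConfig, SimulationConfig, make_benchmark
from .tcn import LatentTemporalFeatures, TCNAutoencoder, TCNConfig

__all__ = [
    "benchmark_tcn_config",
    "benchmark_predictor_config",
    "prepare_benchmark",
    "protocol_comparison",
]


def benchmark_tcn_config(seed: int = 0) -> TCNConfig:
    return TCNConfig(n_blocks=3, channel_schedule=[8, 16, 16], latent_dim=16,
                     epochs=40, seed=seed)


def benchmark_predictor_config(seed: int = 0) -> PredictorConfig:
    return PredictorConfig(epochs=300, seed=seed)


def prepare_benchmark(seed: int, dropout_rate: float | None = None,
                      signal_fraction: float = 0.8
                      ) -> tuple[AlignedDataset, LatentTemporalFeatures]:
    """Generate the default benchmark for one seed and fit its autoencoder.

    The autoencoder is unsupervised, so the temporal features can be shared
    across folds, protocol schemes and control arms for the same seed.
    """
    sim_kw = {} if dropout_rate is None else {"dropout_rate": dropout_rate}
    dataset, _ = make_benchmark(
        SimulationConfig(seed=seed, **sim_kw),
        EmbeddingFixtureConfig(seed=seed, signal_fraction=signal_fraction),
    )
    temporal = TCNAutoencoder(dataset.trajectory, benchmark_tcn_config(seed)).fit().encode()
    return dataset, temporal


def protocol_comparison(dataset: AlignedDataset, temporal: LatentTemporalFeatures,
                        seed: int, scheme: str = "edge_kfold_inverted",
                        k: int = 10, n_folds: int = 3,
                        permute: bool = False) -> ProtocolResults:
    """Run the protocol on the first ``n_folds`` folds of a seeded split.

    ``permute=True`` runs the label-permuted control arm of the same split
    with the same sampled negatives.
    """
    plan = make_split(dataset.edges, scheme, k=k, seed=seed)
    sub = SplitPlan(folds=plan.folds[:n_folds], scheme=plan.scheme, seed=plan.seed)
    return run_protocol(dataset, sub, temporal=temporal,
                        predictor_cfg=benchmark_predictor_config(seed),
                        permute_train_labels=permute)
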