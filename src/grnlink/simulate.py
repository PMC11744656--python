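"""Planted-network benchmark generator.

Produces the three pipeline inputs with known ground truth so every stage and
protocol is testable without external data:

* a planted signed GRN (directed TF -> target edges with random sign and
  weight), standing in for a ChIP-seq-derived label corpus;
* an expression trajectory driven by that GRN through bounded discrete-time
  dynamics with additive Gaussian noise and independent dropout zeroing,
  standing in for pseudotime-ordered scRNA-seq;
* per-gene embedding vectors built as a random projection of each gene's
  signed regulatory context (its adjacency row as a regulator and column as a
  target) mixed with noise, standing in for language-model gene embeddings
  whose similarity tracks shared regulatory context.  ``signal_fraction``
  interpolates from pure noise (0) to pure structure (1) and emulates running
  the pipeline with versus without informative prior embeddings.

The dynamics are deliberately simple: bounded by a tanh squashing of the
summed regulatory input, linear decay, non-negativity clipping.  They are not
a realistic scRNA-seq count model (no library-size effects, no negative
binomial sampling, no branching) -- see the methods note for what this does
and does not validate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigError, SimulationError, StructuralError
from .io import AlignedDataset, EdgeSet, EmbeddingTable, ExpressionTrajectory

__all__ = [
    "SimulationConfig",
    "EmbeddingFixtureConfig",
    "PlantedGRN",
    "generate_grn",
    "simulate_trajectory",
    "generate_embeddings",
    "make_benchmark",
    "write_benchmark",
]


@dataclass
class SimulationConfig:
    """Benchmark scale and dynamics parameters.

    Defaults give the standard small benchmark: 50 genes of which 5 are TFs,
    200 cells along the trajectory, each TF->target edge planted with
    probability 0.15, and 30% dropout.
    """

    n_genes: int = 50
    n_tfs: int = 5
    n_cells: int = 200
    edge_prob: float = 0.15
    noise_sd: float = 0.05
    dropout_rate: float = 0.3
    decay: float = 0.3
    step_size: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_tfs > self.n_genes:
            raise ConfigError("n_tfs cannot exceed n_genes")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if not 0.0 <= self.edge_prob <= 1.0:
            raise ConfigError("edge_prob must be a probability")
        if self.decay <= 0 or self.step_size <= 0:
            raise ConfigError("decay and step_size must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


@dataclass
class EmbeddingFixtureConfig:
    """Structure-correlated embedding fixture.

    ``dim`` defaults to 128, wider than the default benchmark's regulatory
    context (2 x 50 entries), so the random projection is near-injective --
    mirroring the regime of the very high-dimensional text embeddings this
    fixture emulates, whose dimension far exceeds the gene count.
    """

    dim: int = 128
    signal_fraction: float = 0.8
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.dim < 1:
            raise ConfigError("embedding dim must be >= 1")
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ConfigError("signal_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


@dataclass
class PlantedGRN:
    """Ground-truth signed network: edges (tf, target, sign, weight)."""

    genes: list[str]
    tfs: list[str]
    edges: list[tuple[str, str, int, float]]
    seed: int = 0

    def __post_init__(self):
        tfs = set(self.tfs)
        seen = set()
        for tf, tgt, sign, _ in self.edges:
            if tf not in tfs:
                raise StructuralError(f"edge source {tf!r} is not a TF")
            if tf == tgt:
                raise StructuralError(f"self-edge on {tf!r}")
            if (tf, tgt) in seen:
                raise StructuralError(f"duplicate edge {tf}->{tgt}")
            seen.add((tf, tgt))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Signed weighted adjacency W, W[i, j] = weight of gene_i -> gene_j."""
        idx = {g: i for i, g in enumerate(self.genes)}
        W = np.zeros((len(self.genes), len(self.genes)))
        for tf, tgt, _, w in self.edges:
            W[idx[tf], idx[tgt]] = w
        return W

    def to_edgeset(self) -> EdgeSet:
        return EdgeSet([(tf, tgt, 1) for tf, tgt, _, _ in self.edges])


def generate_grn(cfg: SimulationConfig) -> PlantedGRN:
    """Plant each TF -> target edge independently with probability
    ``edge_prob``; sign is +/- with equal probability and |weight| is
    Uniform(0.5, 1.5).  The first ``n_tfs`` genes are the TFs."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:03d}" for i in range(cfg.n_genes)]
    tfs = genes[: cfg.n_tfs]
    draw = rng.random((cfg.n_tfs, cfg.n_genes))
    signs = np.where(rng.random((cfg.n_tfs, cfg.n_genes)) < 0.5, 1, -1)
    mags = rng.uniform(0.5, 1.5, size=(cfg.n_tfs, cfg.n_genes))
    edges = []
    for i in range(cfg.n_tfs):
        for j in range(cfg.n_genes):
            if i == j:
                continue  # no self-edges
            if draw[i, j] < cfg.edge_prob:
                edges.append((tfs[i], genes[j], int(signs[i, j]),
                              float(signs[i, j] * mags[i, j])))
    if not edges:
        raise StructuralError(
            "planted network has zero edges; increase edge_prob or network size")
    return PlantedGRN(genes, tfs, edges, seed=cfg.seed)


def simulate_trajectory(grn: PlantedGRN, cfg: SimulationConfig) -> ExpressionTrajectory:
    """Drive expression along pseudotime with the planted network.

    State update per gene g:
    ``x_g(t+1) = max(0, x_g(t) + step_size * (tanh(sum_r w_rg x_r(t))
    - decay * x_g(t)) + eps)`` with ``eps ~ N(0, noise_sd^2)``; the initial
    state is Uniform(0, 1).  The recorded matrix holds the n_cells successive
    states; afterwards each entry is independently zeroed with probability
    ``dropout_rate``."""
    rng = np.random.default_rng(cfg.seed + 1)  # distinct stream from the GRN draw
    W = grn.adjacency()
    n = len(grn.genes)
    x = rng.uniform(0.0, 1.0, size=n)
    states = np.empty((n, cfg.n_cells))
    states[:, 0] = x
    for t in range(1, cfg.n_cells):
        drive = np.tanh(W.T @ x)
        eps = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0
        x = np.maximum(0.0, x + cfg.step_size * (drive - cfg.decay * x) + eps)
        if not np.all(np.isfinite(x)):
            raise SimulationError(f"non-finite state at simulation step {t}")
        states[:, t] = x
    if cfg.dropout_rate > 0:
        keep = rng.random(states.shape) >= cfg.dropout_rate
        states = states * keep
    cells = [f"cell{t:04d}" for t in range(cfg.n_cells)]
    return ExpressionTrajectory(list(grn.genes), cells, states)


def generate_embeddings(grn: PlantedGRN, cfg: EmbeddingFixtureConfig) -> EmbeddingTable:
    """Embed each gene's regulatory context.

    The context vector ``u_g`` concatenates gene g's adjacency-magnitude row
    (its targets, as a regulator) and column (its regulators, as a target).
    Magnitudes rather than signed weights are used: the fixture emulates
    text-derived knowledge embeddings, which encode *that* genes interact,
    not the direction of the effect -- and because planted edge signs are
    independent coin flips, signed contexts of co-regulated genes would be
    uncorrelated in expectation, defeating the fixture's purpose of making
    shared regulatory context visible as embedding similarity.

    The embedding is ``signal_fraction * (M @ u_g) + (1 - signal_fraction) *
    eta`` with M a seeded random projection to ``dim`` and per-coordinate
    Gaussian noise eta; co-regulated genes embed nearby when the signal
    fraction is high."""
    rng = np.random.default_rng(cfg.seed + 2)
    W = np.abs(grn.adjacency())
    n = len(grn.genes)
    context = np.concatenate([W, W.T], axis=1)  # (n, 2n): row then column parts
    M = rng.normal(0.0, 1.0 / np.sqrt(2 * n), size=(2 * n, cfg.dim))
    noise = rng.normal(0.0, cfg.noise_sd, size=(n, cfg.dim))
    vectors = cfg.signal_fraction * (context @ M) + (1 - cfg.signal_fraction) * noise
    return EmbeddingTable(list(grn.genes), vectors)


def make_benchmark(cfg: SimulationConfig | None = None,
                   emb_cfg: EmbeddingFixtureConfig | None = None
                   ) -> tuple[AlignedDataset, PlantedGRN]:
    """Bundle trajectory, embeddings and the positive edge set into an
    aligned dataset, returning the planted network alongside."""
    cfg = cfg or SimulationConfig()
    emb_cfg = emb_cfg or EmbeddingFixtureConfig(seed=cfg.seed)
    grn = generate_grn(cfg)
    trajectory = simulate_trajectory(grn, cfg)
    embeddings = generate_embeddings(grn, emb_cfg)
    dataset = AlignedDataset(trajectory, embeddings, grn.to_edgeset())
    return dataset, grn


def write_benchmark(out_dir, cfg: SimulationConfig | None = None,
                    emb_cfg: EmbeddingFixtureConfig | None = None,
                    expression_format: str = "dense-tsv") -> dict:
    """Write the three standard benchmark files plus a JSON manifest of every
    seed and parameter; returns the manifest dict."""
    from pathlib import Path

    from .io import write_edges, write_embeddings, write_expression

    cfg = cfg or SimulationConfig()
    emb_cfg = emb_cfg or EmbeddingFixtureConfig(seed=cfg.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, grn = make_benchmark(cfg, emb_cfg)
    expr_name = "expression.tsv" if expression_format == "dense-tsv" else "expression.mtx"
    write_expression(dataset.trajectory, out / expr_name, format=expression_format)
    write_embeddings(dataset.embeddings, out / "embeddings.tsv")
    write_edges(dataset.edges, out / "edges.tsv")
    manifest = {
        "simulation": asdict(cfg),
        "embeddings": asdict(emb_cfg),
        "n_planted_edges": grn.n_edges,
        "files": [expr_name, "embeddings.tsv", "edges.tsv"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
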