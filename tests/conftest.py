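import numpy as np
import pytest

from grnlink.io import EdgeSet, EmbeddingTable, ExpressionTrajectory
from grnlink.simulate import EmbeddingFixtureConfig, SimulationConfig, make_benchmark


@pytest.fixture
def smooth_trajectory():
    """8 genes x 30 cells of smooth phase-shifted sinusoids (non-negative)."""
    rng = np.random.default_rng(0)
    t = np.linspace(0, 2 * np.pi, 30)
    values = np.array([np.sin(t + p) + 1.5 for p in rng.uniform(0, 2 * np.pi, 8)])
    return ExpressionTrajectory(
        [f"G{i}" for i in range(8)], [f"c{j}" for j in range(30)], values
    )


@pytest.fixture(scope="session")
def small_benchmark():
    """A 20-gene / 3-TF / 60-cell planted benchmark, cheap enough for unit tests."""
    dataset, grn = make_benchmark(
        SimulationConfig(n_genes=20, n_tfs=3, n_cells=60, edge_prob=0.3, seed=7),
        EmbeddingFixtureConfig(dim=16, seed=7),
    )
    return dataset, grn


@pytest.fixture
def tiny_embeddings():
    rng = np.random.default_rng(1)
    return EmbeddingTable([f"G{i}" for i in range(6)], rng.normal(size=(6, 4)))


@pytest.fixture
def labeled_edges():
    return EdgeSet(
        [("G0", "G2", 1), ("G0", "G3", 1), ("G1", "G4", 1),
         ("G0", "G4", 0), ("G1", "G2", 0), ("G1", "G5", 0)]
    )
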