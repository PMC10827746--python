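"""Shared fixtures: generated datasets and trained models, all seeded.

The heavier fixtures are session-scoped so several test modules can share
one training run; sizes are kept small (hundreds of cells, a few hundred
genes) so the whole suite stays in the minutes range on one CPU core.
"""

import numpy as np
import pytest

from scdisentangle.simulation import SimulationConfig, hold_out_matrices, simulate
from scdisentangle.training import TrainConfig, fit

FIG_LAYOUT_HOLDOUT = [("batch0", ("ctrl", "severe")),
                      ("batch1", ("stim", "healthy"))]


@pytest.fixture(scope="session")
def quick_truth():
    """Small, strongly perturbed dataset for fast task-level tests."""
    return simulate(SimulationConfig(
        n_cells_per_matrix=60, n_genes=120, m_diff=20, epsilon=8.0,
        n_cell_types=3, seed=11))


@pytest.fixture(scope="session")
def quick_model(quick_truth):
    """Model trained briefly on the full 8-matrix quick dataset."""
    state, log = fit(quick_truth.perturbed,
                     TrainConfig(max_epochs=80, seed=5))
    return state, log


@pytest.fixture(scope="session")
def bench_truth():
    """Benchmark-style grid cell: strong effect, 100 CKGs per type."""
    return simulate(SimulationConfig(
        n_cells_per_matrix=150, n_genes=420, m_diff=100, epsilon=8.0,
        seed=1))


@pytest.fixture(scope="session")
def bench_split(bench_truth):
    """The disentanglement layout: two matrices removed -> 6 train matrices."""
    return hold_out_matrices(bench_truth, FIG_LAYOUT_HOLDOUT)


@pytest.fixture(scope="session")
def bench_model(bench_split):
    train, _ = bench_split
    state, log = fit(train, TrainConfig(max_epochs=170, seed=0))
    return state, log
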