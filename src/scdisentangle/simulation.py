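"""Ground-truthed synthetic multi-batch multi-condition count data.

The base generator is a hierarchical negative-binomial model playing the
statistical roles that matter for this problem: distinct cell types with
their own expression programs, batch-specific technical distortion, broad
per-cell sequencing depths, and overdispersed counts.

* every gene has a log-normal baseline expression level shared by all cells;
* each cell type up- or down-regulates its own random subset of marker
  genes by log-normal fold changes (the "expression program");
* each batch multiplies every gene by its own log-normal distortion factor
  (technical, identical for all cells of the batch);
* per-cell library sizes are log-normal; relative expression is normalized
  per cell and scaled by the library size to give NB means with gene-wise
  dispersion.

Condition effects are injected afterwards: for each condition type a block
of designated condition-associated key genes (CKGs, disjoint across types)
receives a uniform additive shift U(eps-1, eps) in every cell whose label
for that type is not the reference (first) label.  Cells of the reference
label and all non-CKG genes are untouched, so the clean and perturbed
matrices differ exactly on (perturbed cells x CKG columns).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MultiConditionDataset


@dataclass
class SimulationConfig:
    """Study-design knobs for the generator.

    `epsilon` controls the strength of the injected condition effect (the
    additive shift is U(epsilon-1, epsilon) counts); `m_diff` is the number
    of CKGs per condition type.  Defaults mirror the benchmark design:
    2 batches x (treatment: ctrl/stim) x (severity: healthy/severe),
    500 cells per (batch, condition) matrix.
    """

    n_cells_per_matrix: int = 500
    n_genes: int = 500
    n_batches: int = 2
    n_cell_types: int = 3
    condition_design: dict[str, list[str]] = field(default_factory=lambda: {
        "treatment": ["ctrl", "stim"],
        "severity": ["healthy", "severe"],
    })
    m_diff: int = 100
    epsilon: float = 8.0
    batch_effect: float = 0.25       # sd of log-normal gene-wise distortion
    cell_type_effect: float = 1.0    # mean log fold-change of marker genes
    marker_fraction: float = 0.1     # markers per cell type
    library_log_mean: float = np.log(2500.0)
    library_log_sd: float = 0.35
    dispersion_log_mean: float = np.log(5.0)
    dispersion_log_sd: float = 0.5
    seed: int = 0

    @property
    def condition_types(self) -> list[str]:
        return list(self.condition_design.keys())

    @property
    def n_condition_types(self) -> int:
        return len(self.condition_design)

    def ckg_sets(self) -> list[np.ndarray]:
        """CKG index blocks: first m_diff genes for type 1, next for type 2, ..."""
        sets = []
        start = 0
        for _ in range(self.n_condition_types):
            sets.append(np.arange(start, start + self.m_diff))
            start += self.m_diff
        return sets

    def validate(self) -> None:
        if self.epsilon < 1:
            raise ValueError("epsilon must be >= 1")
        if self.m_diff < 1:
            raise ValueError("m_diff must be >= 1")
        if 2 * self.m_diff * self.n_condition_types > self.n_genes:
            raise ValueError(
                f"{self.m_diff} CKGs x {self.n_condition_types} condition types "
                f"need at most {self.n_genes // 2} genes each "
                f"(2*sum(m_diff) <= n_genes)")
        for t, labels in self.condition_design.items():
            if len(labels) < 2:
                raise ValueError(f"condition type {t!r} needs >= 2 labels")
        if int(self.marker_fraction * self.n_genes) < 1:
            raise ValueError("marker_fraction yields no marker genes")


@dataclass
class SimulationTruth:
    """A generated dataset plus everything needed to score methods on it."""

    clean: MultiConditionDataset
    perturbed: MultiConditionDataset
    ckg_sets: list[np.ndarray]            # per condition type
    config: SimulationConfig

    @property
    def dataset(self) -> MultiConditionDataset:
        return self.perturbed

    def matrix_mask(self, batch: str, combo: tuple[str, ...]) -> np.ndarray:
        """Boolean mask of cells in one (batch, condition combination) matrix."""
        ds = self.perturbed
        m = ds.batches.to_numpy().astype(str) == str(batch)
        for col, lab in zip(ds.conditions.columns, combo):
            m &= ds.conditions[col].to_numpy().astype(str) == str(lab)
        return m


def simulate_base(cfg: SimulationConfig) -> SimulationTruth:
    """Clean (no condition effect) multi-batch dataset with known cell types."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    g, b = cfg.n_genes, cfg.n_batches
    combos = list(itertools.product(*cfg.condition_design.values()))
    n_per_batch = cfg.n_cells_per_matrix * len(combos)
    n = n_per_batch * b

    base = rng.lognormal(0.0, 1.0, size=g)
    n_markers = int(cfg.marker_fraction * g)
    type_effect = np.ones((cfg.n_cell_types, g))
    for t in range(cfg.n_cell_types):
        markers = rng.choice(g, size=n_markers, replace=False)
        sign = rng.choice([-1.0, 1.0], size=n_markers)
        type_effect[t, markers] = np.exp(
            sign * rng.normal(cfg.cell_type_effect, 0.25, size=n_markers))
    batch_effect = np.exp(rng.normal(0.0, cfg.batch_effect, size=(b, g)))
    theta = rng.lognormal(cfg.dispersion_log_mean, cfg.dispersion_log_sd, size=g)

    cell_types = rng.integers(0, cfg.n_cell_types, size=n)
    batches = np.repeat(np.arange(b), n_per_batch)
    library = rng.lognormal(cfg.library_log_mean, cfg.library_log_sd, size=n)

    rel = base[None, :] * type_effect[cell_types] * batch_effect[batches]
    rel /= rel.sum(axis=1, keepdims=True)
    mu = rel * library[:, None]
    counts = rng.poisson(rng.gamma(shape=theta[None, :], scale=mu / theta[None, :]))

    # evenly separate each batch's cells into the condition combinations
    # (seeded shuffle, then contiguous equal blocks)
    combo_idx = np.empty(n, dtype=np.int64)
    for j in range(b):
        idx = np.flatnonzero(batches == j)
        idx = rng.permutation(idx)
        for ci, chunk in enumerate(np.array_split(idx, len(combos))):
            combo_idx[chunk] = ci

    conditions = pd.DataFrame(
        [combos[i] for i in combo_idx], columns=cfg.condition_types)
    ds = MultiConditionDataset(
        counts=counts,
        gene_ids=[f"gene{i}" for i in range(g)],
        batches=pd.Series([f"batch{j}" for j in batches]),
        conditions=conditions,
        cell_types=pd.Series([f"type{t}" for t in cell_types]),
    )
    return SimulationTruth(clean=ds, perturbed=ds, ckg_sets=cfg.ckg_sets(),
                           config=cfg)


def add_condition_effect(truth: SimulationTruth, cfg: SimulationConfig | None = None,
                         round_counts: bool = True) -> SimulationTruth:
    """Inject additive U(eps-1, eps) shifts on CKGs of non-reference labels.

    The first label of each condition type is its reference (no effect).
    Rounding is half-to-even with a floor at zero; pass
    ``round_counts=False`` for the continuous variant.
    """
    cfg = cfg or truth.config
    sets = truth.ckg_sets
    flat = np.concatenate(sets) if sets else np.array([], dtype=int)
    if len(np.unique(flat)) != len(flat):
        raise ValueError("CKG sets of different condition types must be disjoint")
    clean = truth.clean
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    x = clean.counts.astype(np.float64).copy()
    for k, tname in enumerate(clean.condition_types):
        ref_label = cfg.condition_design[tname][0]
        labels = clean.conditions[clean.conditions.columns[k]].to_numpy().astype(str)
        perturbed_cells = np.flatnonzero(labels != str(ref_label))
        if len(perturbed_cells) == 0:
            continue
        genes = sets[k]
        shift = rng.uniform(cfg.epsilon - 1.0, cfg.epsilon,
                            size=(len(perturbed_cells), len(genes)))
        x[np.ix_(perturbed_cells, genes)] += shift
    if round_counts:
        x = np.maximum(np.rint(x), 0.0).astype(np.int64)
        perturbed = MultiConditionDataset(
            counts=x,
            gene_ids=list(clean.gene_ids),
            batches=clean.batches,
            conditions=clean.conditions,
            cell_types=clean.cell_types,
        )
    else:
        perturbed = _continuous_dataset(clean, np.maximum(x, 0.0))
    perturbed._relevel(clean.batch_levels, clean.condition_levels)
    return SimulationTruth(clean=clean, perturbed=perturbed,
                           ckg_sets=truth.ckg_sets, config=cfg)


def _continuous_dataset(clean: MultiConditionDataset,
                        x: np.ndarray) -> MultiConditionDataset:
    # bypass the integer check for the unrounded variant
    ds = MultiConditionDataset(
        counts=np.zeros_like(clean.counts), gene_ids=list(clean.gene_ids),
        batches=clean.batches, conditions=clean.conditions,
        cell_types=clean.cell_types)
    ds.counts = x
    return ds


def simulate(cfg: SimulationConfig, round_counts: bool = True) -> SimulationTruth:
    """Base simulation followed by condition-effect injection."""
    return add_condition_effect(simulate_base(cfg), cfg, round_counts)


GRID_M_DIFF = (20, 50, 100)
GRID_EPSILON = (2.0, 4.0, 8.0)


def make_benchmark_grid(base_cfg: SimulationConfig | None = None
                        ) -> dict[tuple[int, float], SimulationTruth]:
    """The 9-dataset benchmark: m_diff in {20,50,100} x epsilon in {2,4,8}.

    Each dataset has 2 batches x 4 condition combinations = 8 count
    matrices; CKGs of type 1 are the first m_diff genes, of type 2 the next
    m_diff.  Deterministic per (grid cell, seed).
    """
    from dataclasses import replace

    base_cfg = base_cfg or SimulationConfig()
    grid = {}
    for m in GRID_M_DIFF:
        for eps in GRID_EPSILON:
            cfg = replace(base_cfg, m_diff=m, epsilon=eps)
            grid[(m, eps)] = simulate(cfg)
    return grid


def hold_out_matrices(truth: SimulationTruth,
                      spec: list[tuple[str, tuple[str, ...]]]
                      ) -> tuple[MultiConditionDataset, MultiConditionDataset | None]:
    """Split cells into train / held-out by (batch, condition combination).

    `spec` lists matrices to hold out, e.g. ``[("batch0", ("ctrl","severe"))]``.
    Raises if holding out would leave a condition label with no training
    occurrence at all (it would become untrainable).
    """
    ds = truth.perturbed
    held = np.zeros(ds.n_cells, dtype=bool)
    for batch, combo in spec:
        m = truth.matrix_mask(batch, combo)
        if not m.any():
            raise ValueError(f"no cells in matrix ({batch}, {combo})")
        held |= m
    if not held.any():
        return ds, None
    train = ds.subset(~held)
    for k, col in enumerate(ds.conditions.columns):
        missing = (set(np.unique(ds.condition_codes[:, k]))
                   - set(np.unique(train.condition_codes[:, k])))
        if missing:
            labs = [ds.condition_levels[k][m] for m in missing]
            raise ValueError(
                f"hold-out leaves condition labels {labs} of type {col!r} "
                "with no training cells")
    return train, ds.subset(held)
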