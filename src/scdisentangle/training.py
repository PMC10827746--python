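"""Alternating two-step stochastic optimization of the objective.

Each minibatch is processed twice.  Step 1 freezes the unshared encoders,
classifiers and mixture-prior parameters and takes one Adam step on the
shared encoder + decoder minimizing

``L_s1 = -recon + l_kl1 * KL(z_s) + l_mmd * MMD(z_s)``.

Step 2 freezes the shared encoder and takes one Adam step on the unshared
encoders, classifiers, prior parameters and decoder minimizing

``L_s2 = -recon + l_kl2 * KL(z_u) + l_mmd * MMD(z_u) + l_ce * CE + l_gl * GL``.

One Adam instance per partition keeps moment statistics consistent with the
freezing scheme (the decoder, updated in both steps, carries a moment state
in each).  Everything — initialization, shuffling, dropout, reparameterized
sampling — is driven by a single seed, so a run is exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor
from .data import MultiConditionDataset, make_batch_factors
from .losses import LossBreakdown, LossWeights, compute_losses
from .model import ModelConfig, ModelState


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    minibatch_size: int = 64
    max_epochs: int = 200
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    model: ModelConfig = field(default_factory=ModelConfig)
    convergence_window: int = 10
    convergence_tol: float = 1e-4
    mmd_min_group: int = 5    # skip smaller groups inside a minibatch

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.minibatch_size < 2:
            raise ValueError("minibatch_size must be >= 2")


class TrainingDiverged(RuntimeError):
    pass


def _weighted(terms: dict[str, Tensor], coeffs: dict[str, float]) -> Tensor:
    total = None
    for name, c in coeffs.items():
        if c == 0.0:
            continue
        t = terms[name] * c
        total = t if total is None else total + t
    return total if total is not None else Tensor(0.0)


def train_step_shared(counts, bfac, cond, state: ModelState, weights: LossWeights,
                      opt: Adam, rng: np.random.Generator,
                      min_group: int = 5, library=None,
                      x_pre=None, lgamma_x1=None) -> dict[str, float]:
    """One Adam step on shared encoder + decoder (L_s1); others untouched."""
    terms = compute_losses(counts, bfac, cond, state, weights, library,
                           rng, min_group, x_pre, lgamma_x1)
    loss = _weighted(terms, {
        "reconstruction": -1.0,
        "kl_shared": weights.lambda_kl1,
        "mmd_shared": weights.lambda_mmd,
    })
    opt.zero_grad()
    loss.backward()
    _check_finite(state.partition("shared") | state.partition("decoder"), terms)
    opt.step()
    return {k: v.item() for k, v in terms.items()}


def train_step_unshared(counts, bfac, cond, state: ModelState, weights: LossWeights,
                        opt: Adam, rng: np.random.Generator,
                        min_group: int = 5, library=None,
                        x_pre=None, lgamma_x1=None) -> dict[str, float]:
    """One Adam step on unshared encoders/classifiers/priors + decoder (L_s2)."""
    terms = compute_losses(counts, bfac, cond, state, weights, library,
                           rng, min_group, x_pre, lgamma_x1)
    loss = _weighted(terms, {
        "reconstruction": -1.0,
        "kl_unshared": weights.lambda_kl2,
        "mmd_unshared": weights.lambda_mmd,
        "cross_entropy": weights.lambda_ce,
        "group_lasso": weights.lambda_gl,
    })
    opt.zero_grad()
    loss.backward()
    _check_finite(state.partition("unshared") | state.partition("decoder"), terms)
    opt.step()
    return {k: v.item() for k, v in terms.items()}


def _check_finite(params: dict[str, Tensor], terms: dict[str, Tensor]) -> None:
    for name, p in params.items():
        if p.grad is not None and not np.all(np.isfinite(p.grad)):
            bad = {k: v.item() for k, v in terms.items()}
            raise TrainingDiverged(
                f"non-finite gradient in {name}; loss terms: {bad}")


def fit(ds: MultiConditionDataset, config: TrainConfig | None = None,
        log_path=None) -> tuple[ModelState, pd.DataFrame]:
    """Train on a dataset; returns the fitted state and a per-epoch loss log.

    Stops at `max_epochs` or when the relative improvement of the windowed
    epoch-mean total loss drops below `convergence_tol`.
    """
    config = config or TrainConfig()
    for k, levels in enumerate(ds.condition_levels):
        present = np.unique(ds.condition_codes[:, k])
        if len(present) < 2:
            raise ValueError(
                f"condition type {ds.condition_types[k]!r} has a single label "
                "in the training data; need >= 2")
    if ds.n_batches == 1 and len(np.unique(ds.group_keys(), axis=0)) == 1:
        warnings.warn("single batch and single condition combination: "
                      "batch/condition disentanglement is unidentifiable")

    rng = np.random.default_rng(config.seed)
    lib = ds.library_sizes()
    state = ModelState.initialize(
        n_genes=ds.n_genes, n_batches=ds.n_batches,
        n_labels=[len(l) for l in ds.condition_levels],
        batch_levels=ds.batch_levels, condition_types=ds.condition_types,
        condition_levels=ds.condition_levels, gene_ids=ds.gene_ids,
        median_library=float(np.median(lib)), config=config.model,
        seed=int(rng.integers(2**31)))
    opt1 = Adam(state.partition("shared") | state.partition("decoder"),
                lr=config.learning_rate)
    opt2 = Adam(state.partition("unshared") | state.partition("decoder"),
                lr=config.learning_rate)

    bfac = make_batch_factors(ds)
    cond = ds.condition_codes
    counts = ds.counts
    from scipy.special import gammaln as _gammaln

    from .model import model_input, preprocess
    raw_in = preprocess(counts, state.median_library, lib)
    state.gene_log_mean = raw_in.mean(axis=0)
    state.gene_log_std = raw_in.std(axis=0)
    x_pre_all = model_input(state, counts, lib)
    lgx_all = _gammaln(counts.astype(np.float64) + 1.0)
    n = ds.n_cells
    w = config.weights
    log_rows = []
    history = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        acc: dict[str, float] = {}
        nb = 0
        for start in range(0, n, config.minibatch_size):
            idx = order[start:start + config.minibatch_size]
            if len(idx) < 2:
                continue
            t1 = train_step_shared(counts[idx], bfac[idx], cond[idx], state, w,
                                   opt1, rng, config.mmd_min_group, lib[idx],
                                   x_pre_all[idx], lgx_all[idx])
            t2 = train_step_unshared(counts[idx], bfac[idx], cond[idx], state, w,
                                     opt2, rng, config.mmd_min_group, lib[idx],
                                     x_pre_all[idx], lgx_all[idx])
            merged = {"reconstruction": t2["reconstruction"],
                      "kl_shared": t1["kl_shared"],
                      "kl_unshared": t2["kl_unshared"],
                      "mmd_shared": t1["mmd_shared"],
                      "mmd_unshared": t2["mmd_unshared"],
                      "cross_entropy": t2["cross_entropy"],
                      "group_lasso": t2["group_lasso"]}
            for k, v in merged.items():
                acc[k] = acc.get(k, 0.0) + v
            nb += 1
        mean_terms = {k: v / nb for k, v in acc.items()}
        bd = LossBreakdown.combine(**mean_terms, w=w)
        if not np.isfinite(bd.total):
            raise TrainingDiverged(f"total loss became {bd.total} at epoch {epoch}")
        log_rows.append({"epoch": epoch, **vars(bd)})
        history.append(bd.total)
        win = config.convergence_window
        if len(history) > 2 * win:
            prev = np.mean(history[-2 * win:-win])
            cur = np.mean(history[-win:])
            if abs(prev - cur) / max(abs(prev), 1e-12) < config.convergence_tol:
                break

    _cache_label_latent_means(state, ds)
    log = pd.DataFrame(log_rows)
    if log_path is not None:
        log.to_csv(log_path, sep="\t", index=False)
    return state, log


def _cache_label_latent_means(state: ModelState, ds: MultiConditionDataset) -> None:
    """Per condition type, cache mean unshared posterior means per label.

    These are the anchors of the perturbation-prediction shifting vectors,
    stored with the model so prediction never needs the training data.
    """
    from .model import encode_unshared, model_input

    x_in = model_input(state, ds.counts, ds.library_sizes())
    means = []
    for k in range(state.n_condition_types):
        mu_u, _ = encode_unshared(x_in, state, k)
        per_label = np.zeros((state.n_labels[k], state.config.d_u))
        for c in range(state.n_labels[k]):
            sel = ds.condition_codes[:, k] == c
            if sel.any():
                per_label[c] = mu_u.data[sel].mean(axis=0)
            else:
                per_label[c] = np.nan
        means.append(per_label)
    state.label_latent_means = means


def evaluate_losses(ds: MultiConditionDataset, state: ModelState,
                    weights: LossWeights) -> LossBreakdown:
    """Forward-only loss computation: dropout off, posterior means, no updates.

    Deterministic — two invocations agree bit for bit.  MMD grouping uses
    the full dataset, so values are comparable across train/test splits.
    """
    missing = set(ds.batch_levels) - set(state.batch_levels)
    if set(ds.batch_levels).isdisjoint(state.batch_levels):
        raise ValueError(
            f"no overlap between data batches {ds.batch_levels} and training "
            f"batches {state.batch_levels}")
    if missing:
        raise ValueError(f"batches {sorted(missing)} were not seen in training")
    bfac = np.zeros((ds.n_cells, state.n_batches))
    lookup = {v: i for i, v in enumerate(state.batch_levels)}
    bfac[np.arange(ds.n_cells),
         [lookup[str(v)] for v in ds.batches]] = 1.0
    cond = _recode_conditions(ds, state)
    terms = compute_losses(ds.counts, bfac, cond, state, weights,
                           ds.library_sizes(), rng=None, min_group=1)
    return LossBreakdown.combine(
        **{k: v.item() for k, v in terms.items()}, w=weights)


def _recode_conditions(ds: MultiConditionDataset, state: ModelState) -> np.ndarray:
    cols = []
    for k, col in enumerate(ds.conditions.columns):
        lookup = {v: i for i, v in enumerate(state.condition_levels[k])}
        try:
            cols.append(np.array([lookup[str(v)] for v in ds.conditions[col]]))
        except KeyError as e:
            raise ValueError(
                f"condition label {e} of type {col!r} was not seen in training"
            ) from None
    return np.stack(cols, axis=1)
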