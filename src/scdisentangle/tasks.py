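"""Headline capabilities of a trained model.

* :func:`extract_latent` — batch-corrected cell embeddings (posterior means);
* :func:`ckg_scores` — per-gene condition-association scores from the
  group-lasso-regularized first layer of each unshared encoder;
* :func:`denoise` — the decoder's NB mean for each cell under its own batch
  and conditions;
* :func:`predict_perturbation` — any-to-any prediction across condition
  labels and batches by latent-space arithmetic: shift each z_u block by the
  difference of training-label latent centroids, swap the batch one-hot,
  keep z_s untouched, decode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .data import MultiConditionDataset
from .model import (ModelState, decode, encode_shared, encode_unshared,
                    model_input)
from .training import _recode_conditions


@dataclass
class LatentFactors:
    """Per-cell posterior means: z_s (n x d_s), one z_u block per type."""

    z_s: np.ndarray
    z_u: list[np.ndarray]


@dataclass
class CKGScores:
    """Per-gene scores s_i = ||w_i||_2, one vector per condition type."""

    condition_types: list[str]
    gene_ids: list[str]
    scores: list[np.ndarray]

    def ranking(self, k: int) -> "np.ndarray":
        """Gene indices of condition type k sorted by descending score."""
        return np.argsort(-self.scores[k], kind="stable")


@dataclass
class PredictionRequest:
    """Target state for perturbation prediction.

    `target_labels` maps condition type name -> target label (types omitted
    are left unchanged); `target_batch` defaults to each cell's own batch.
    """

    target_labels: dict[str, str]
    target_batch: str | None = None


def _check_genes(ds: MultiConditionDataset, state: ModelState) -> None:
    if list(ds.gene_ids) != list(state.gene_ids):
        missing = sorted(set(state.gene_ids) - set(ds.gene_ids))
        raise ValueError(
            f"gene set differs from training; {len(missing)} training genes "
            f"missing (first few: {missing[:5]})")


def _batch_factors_for(ds: MultiConditionDataset, state: ModelState) -> np.ndarray:
    lookup = {v: i for i, v in enumerate(state.batch_levels)}
    try:
        codes = [lookup[str(v)] for v in ds.batches]
    except KeyError as e:
        raise ValueError(f"batch {e} was not seen in training") from None
    b = np.zeros((ds.n_cells, state.n_batches))
    b[np.arange(ds.n_cells), codes] = 1.0
    return b


def extract_latent(ds: MultiConditionDataset, state: ModelState) -> LatentFactors:
    """Deterministic posterior means of z_s and every z_u block."""
    _check_genes(ds, state)
    x_in = model_input(state, ds.counts, ds.library_sizes())
    bfac = _batch_factors_for(ds, state)
    mu_s, _ = encode_shared(x_in, bfac, state)
    z_u = []
    for k in range(state.n_condition_types):
        mu_u, _ = encode_unshared(x_in, state, k)
        z_u.append(mu_u.data)
    return LatentFactors(z_s=mu_s.data, z_u=z_u)


def ckg_scores(state: ModelState) -> CKGScores:
    """l2 norms of each gene's first-layer weight column, per condition type."""
    scores = []
    for k in range(state.n_condition_types):
        w = state.params[f"enc_u{k}.w1"].data   # genes x hidden
        scores.append(np.linalg.norm(w, axis=1))
    return CKGScores(condition_types=list(state.condition_types),
                     gene_ids=list(state.gene_ids), scores=scores)


def denoise(ds: MultiConditionDataset, state: ModelState) -> np.ndarray:
    """Decoder NB mean under each cell's own batch and conditions.

    A pure forward pass on posterior means; per-cell outputs sum to the
    cell's observed library size.
    """
    _check_genes(ds, state)
    x_in = model_input(state, ds.counts, ds.library_sizes())
    bfac = _batch_factors_for(ds, state)
    mu_s, _ = encode_shared(x_in, bfac, state)
    z_us = []
    for k in range(state.n_condition_types):
        mu_u, _ = encode_unshared(x_in, state, k)
        z_us.append(mu_u)
    mu, _ = decode(mu_s, z_us, bfac, state, ds.library_sizes())
    return mu.data


def shift_vector(state: ModelState, k: int, source: str,
                 target: str) -> np.ndarray:
    """delta = mean z_u(target) - mean z_u(source) for condition type k."""
    if state.label_latent_means is None:
        raise ValueError("model carries no cached label latent means; "
                         "was it trained with fit()?")
    levels = state.condition_levels[k]
    for lab in (source, target):
        if lab not in levels:
            raise ValueError(
                f"label {lab!r} of condition type "
                f"{state.condition_types[k]!r} was not seen in training")
    d = (state.label_latent_means[k][levels.index(target)]
         - state.label_latent_means[k][levels.index(source)])
    if not np.all(np.isfinite(d)):
        raise ValueError(
            f"no training cells anchored label {source!r} or {target!r}")
    return d


def predict_perturbation(ds: MultiConditionDataset, state: ModelState,
                         request: PredictionRequest,
                         sample: bool = False,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Predict each cell's expression under other condition labels / batch.

    z_s stays exactly as encoded; each z_u block whose target label differs
    from the cell's current label is shifted by the training-centroid
    difference; the batch one-hot is replaced by the target batch.  Returns
    the decoder mean (denoised counts); with ``sample=True``, integer NB
    draws instead.
    """
    _check_genes(ds, state)
    cond = _recode_conditions(ds, state)
    x_in = model_input(state, ds.counts, ds.library_sizes())
    bfac = _batch_factors_for(ds, state)
    mu_s, _ = encode_shared(x_in, bfac, state)

    z_us = []
    for k, tname in enumerate(state.condition_types):
        mu_u, _ = encode_unshared(x_in, state, k)
        z = mu_u.data.copy()
        if tname in request.target_labels:
            tgt = str(request.target_labels[tname])
            levels = state.condition_levels[k]
            if tgt not in levels:
                raise ValueError(
                    f"target label {tgt!r} of type {tname!r} not seen in training")
            for c in np.unique(cond[:, k]):
                src = levels[c]
                if src == tgt:
                    continue
                z[cond[:, k] == c] += shift_vector(state, k, src, tgt)
        z_us.append(Tensor(z))

    if request.target_batch is not None:
        tb = str(request.target_batch)
        if tb not in state.batch_levels:
            raise ValueError(f"target batch {tb!r} was not seen in training")
        bfac = np.zeros_like(bfac)
        bfac[:, state.batch_levels.index(tb)] = 1.0

    mu, theta = decode(mu_s, z_us, bfac, state, ds.library_sizes())
    if not sample:
        return mu.data
    rng = rng or np.random.default_rng()
    t = theta.data[None, :]
    return rng.poisson(rng.gamma(shape=t, scale=mu.data / t)).astype(np.int64)


def export_ckg_ranking(scores: CKGScores, k: int, path) -> None:
    """Two-column TSV (gene_id, score), descending by score."""
    order = scores.ranking(k)
    with open(path, "w") as f:
        f.write("gene_id\tscore\n")
        for i in order:
            f.write(f"{scores.gene_ids[i]}\t{scores.scores[k][i]:.10g}\n")
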