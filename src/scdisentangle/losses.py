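"""Objective terms: NB reconstruction, KL regularizers, MMD alignment,
condition classification cross-entropy, and group-lasso gene selection.

The total objective is

``-E[log NB(x | z_s, z_u, b)] + l_kl1 * KL(q(z_s) || N(0,I))
  + l_kl2 * KL(q(z_u) || N(mu_c, sigma_c^2 I)) + l_gl * GL(W)
  + l_mmd * (MMD(z_s) + MMD(z_u)) + l_ce * CE(y, y_hat)``

with the MMD terms aligning z_s across all (batch, condition) groups and
each z_u block across batches (and labels of the *other* condition types)
within each of its own labels.  Every component is exposed on its own so it
can be tested against closed forms and brute-force oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .model import (ModelState, classify_condition, decode, encode_shared,
                    encode_unshared, nb_log_likelihood, sample_latent)


@dataclass
class LossWeights:
    """Weights of the objective's terms (defaults are the recommended set)."""

    lambda_kl1: float = 1e-5
    lambda_kl2: float = 1e-2
    lambda_mmd: float = 1e-4
    lambda_ce: float = 1.0
    lambda_gl: float = 1.0

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


@dataclass
class LossBreakdown:
    """Scalar value of each objective component plus the weighted total."""

    reconstruction: float
    kl_shared: float
    kl_unshared: float
    mmd_shared: float
    mmd_unshared: float
    cross_entropy: float
    group_lasso: float
    total: float

    @classmethod
    def combine(cls, reconstruction, kl_shared, kl_unshared, mmd_shared,
                mmd_unshared, cross_entropy, group_lasso,
                w: LossWeights) -> "LossBreakdown":
        total = (-reconstruction + w.lambda_kl1 * kl_shared
                 + w.lambda_kl2 * kl_unshared + w.lambda_gl * group_lasso
                 + w.lambda_mmd * (mmd_shared + mmd_unshared)
                 + w.lambda_ce * cross_entropy)
        return cls(reconstruction, kl_shared, kl_unshared, mmd_shared,
                   mmd_unshared, cross_entropy, group_lasso, total)


# -- KL terms ---------------------------------------------------------------


def kl_standard_normal(mu: Tensor, log_var: Tensor) -> Tensor:
    """Mean over cells of KL(N(mu, diag(exp(log_var))) || N(0, I))."""
    kl = 0.5 * (ad.exp(log_var) + mu * mu - 1.0 - log_var)
    return kl.sum(axis=-1).mean()


def kl_gaussian_prior(mu: Tensor, log_var: Tensor, labels: np.ndarray,
                      prior_mu: Tensor, prior_log_sigma: Tensor) -> Tensor:
    """Mean over cells of KL against each cell's own prior component.

    Because every cell's condition label is observed, the mixture prior
    reduces per cell to the single component N(mu_c, sigma_c^2 I) with
    scalar sigma_c.  Differentiable w.r.t. the prior parameters.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= prior_mu.shape[0]:
        raise ValueError("condition label out of range of prior components")
    pm = prior_mu[labels]                             # n x d
    pls = prior_log_sigma[labels].reshape(-1, 1)      # n x 1
    diff = mu - pm
    kl = (pls - 0.5 * log_var
          + (ad.exp(log_var) + diff * diff) * 0.5 * ad.exp(-2.0 * pls)
          - 0.5)
    return kl.sum(axis=-1).mean()


# -- MMD --------------------------------------------------------------------

MMD_BANDWIDTH_SCALES = (0.5, 1.0, 2.0)


def _pairwise_sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aa = (a * a).sum(axis=1)[:, None]
    bb = (b * b).sum(axis=1)[None, :]
    return np.maximum(aa + bb - 2.0 * a @ b.T, 0.0)


def _median_bandwidth(pooled: np.ndarray) -> float:
    d2 = _pairwise_sq_dists(pooled, pooled)
    iu = np.triu_indices(len(pooled), k=1)
    med = np.median(np.sqrt(d2[iu])) if len(iu[0]) else 0.0
    return med if med > 0 else 1.0


def _kernel_mean(a: Tensor, b: Tensor, bandwidths: np.ndarray) -> Tensor:
    """Mean over all pairs of the multi-bandwidth Gaussian kernel."""
    aa = (a * a).sum(axis=1).reshape(-1, 1)
    bb = (b * b).sum(axis=1).reshape(1, -1)
    d2 = aa + bb - 2.0 * (a @ b.T)
    total = None
    for h in bandwidths:
        k = ad.exp(d2 * (-1.0 / (2.0 * h * h)))
        total = k if total is None else total + k
    return total.mean()


def mmd(sample_a, sample_b) -> Tensor:
    """Squared MMD V-statistic under a sum of Gaussian RBF kernels.

    Bandwidths are {m/2, m, 2m} with m the median pairwise distance of the
    pooled sample (recomputed per call, treated as a constant for
    gradients).  Symmetric; zero when the samples coincide as multisets.
    """
    a = sample_a if isinstance(sample_a, Tensor) else Tensor(np.atleast_2d(sample_a))
    b = sample_b if isinstance(sample_b, Tensor) else Tensor(np.atleast_2d(sample_b))
    if a.data.size == 0 or b.data.size == 0:
        raise ValueError("MMD requires two nonempty samples")
    if a.data.shape[1] != b.data.shape[1]:
        raise ValueError("MMD samples must share dimensionality")
    pooled = np.concatenate([a.data, b.data], axis=0)
    bw = _median_bandwidth(pooled) * np.asarray(MMD_BANDWIDTH_SCALES)
    return (_kernel_mean(a, a, bw) + _kernel_mean(b, b, bw)
            - 2.0 * _kernel_mean(a, b, bw))


def _group_slices(keys: np.ndarray) -> list[tuple[tuple, np.ndarray]]:
    """Index arrays per unique key row, ordered by key (categorical order)."""
    keys = np.atleast_2d(np.asarray(keys))
    uniq, inv = np.unique(keys, axis=0, return_inverse=True)
    return [(tuple(uniq[i]), np.flatnonzero(inv == i)) for i in range(len(uniq))]


def _ref_first(groups: list[tuple[tuple, np.ndarray]]) -> int:
    """Largest group; ties broken by first in categorical (key) order."""
    sizes = [len(idx) for _, idx in groups]
    return int(np.argmax(sizes))    # argmax takes first maximum → key order


def mmd_shared(z_s: Tensor, group_keys: np.ndarray,
               min_group: int = 1) -> Tensor:
    """Sum of MMDs between the largest (batch x condition) group and the rest.

    `group_keys` is one row per cell over (batch code, all condition codes).
    Groups smaller than `min_group` are skipped.
    """
    groups = [(k, idx) for k, idx in _group_slices(group_keys)
              if len(idx) >= min_group]
    if len(groups) < 2:
        if len(groups) <= 1:
            warnings.warn("fewer than 2 groups for shared-factor MMD; returning 0")
        return Tensor(0.0)
    ref = _ref_first(groups)
    total = Tensor(0.0)
    for i, (_, idx) in enumerate(groups):
        if i == ref:
            continue
        total = total + mmd(z_s[groups[ref][1]], z_s[idx])
    return total


def mmd_unshared(z_u: Tensor, labels: np.ndarray, extended_batch: np.ndarray,
                 min_group: int = 1) -> Tensor:
    """Per-label alignment of z_u across extended batches.

    For each condition label c of this type, cells carrying c are grouped by
    "extended batch" (batch x labels of all other condition types); the MMD
    between the largest such group and every other is summed.  Cells with
    different labels of this type are never compared.
    """
    labels = np.asarray(labels)
    total = Tensor(0.0)
    for c in np.unique(labels):
        sel = np.flatnonzero(labels == c)
        groups = [(k, sel[idx]) for k, idx in
                  _group_slices(np.atleast_2d(extended_batch)[sel])
                  if len(idx) >= min_group]
        if len(groups) < 2:
            continue
        ref = _ref_first(groups)
        for i, (_, idx) in enumerate(groups):
            if i != ref:
                total = total + mmd(z_u[groups[ref][1]], z_u[idx])
    return total


# -- sparsity and classification -------------------------------------------


def group_lasso(w_first: Tensor) -> Tensor:
    """Sum over genes of the l2 norm of each gene's first-layer weights.

    `w_first` is stored (genes x hidden); each row is one gene's column
    vector in the conventional (hidden x genes) orientation.
    """
    return ad.sqrt((w_first * w_first).sum(axis=1)).sum()


def cross_entropy(labels: np.ndarray, logits: Tensor) -> Tensor:
    """Mean negative log-probability of the true label under softmax logits."""
    labels = np.asarray(labels, dtype=np.int64)
    n, c = logits.shape
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= c:
        raise ValueError("label out of range for logits")
    lse = ad.logsumexp(logits, axis=1)
    true_logit = logits[np.arange(n), labels]
    return (lse - true_logit).mean()


# -- full objective ---------------------------------------------------------


def compute_losses(counts: np.ndarray, batch_factors: np.ndarray,
                   condition_codes: np.ndarray, state: ModelState,
                   weights: LossWeights, library: np.ndarray | None = None,
                   rng: np.random.Generator | None = None,
                   min_group: int = 1,
                   x_pre: np.ndarray | None = None,
                   lgamma_x1: np.ndarray | None = None) -> dict[str, Tensor]:
    """Forward pass through the full model, returning each term as a Tensor.

    Training mode (dropout + reparameterized sampling) is enabled by passing
    `rng`; without it the pass is deterministic on posterior means.
    `x_pre` / `lgamma_x1` allow the caller to reuse the preprocessed inputs
    and the constant lgamma(x+1) term across epochs.
    """
    from .model import model_input

    counts = np.atleast_2d(counts)
    lib = counts.sum(axis=1).astype(np.float64) if library is None else library
    x_in = model_input(state, counts, lib) if x_pre is None else x_pre
    cond = np.atleast_2d(condition_codes)
    keys = np.column_stack([np.argmax(batch_factors, axis=1), cond])

    mu_s, lv_s = encode_shared(x_in, batch_factors, state, rng)
    z_s = sample_latent(mu_s, lv_s, rng) if rng is not None else mu_s
    kl_s = kl_standard_normal(mu_s, lv_s)

    z_us, kl_u, ce, gl = [], Tensor(0.0), Tensor(0.0), Tensor(0.0)
    mmd_u = Tensor(0.0)
    for k in range(state.n_condition_types):
        mu_u, lv_u = encode_unshared(x_in, state, k, rng)
        z_u = sample_latent(mu_u, lv_u, rng) if rng is not None else mu_u
        z_us.append(z_u)
        kl_u = kl_u + kl_gaussian_prior(
            mu_u, lv_u, cond[:, k],
            state.params[f"prior{k}.mu"], state.params[f"prior{k}.log_sigma"])
        clf_in = z_u if (state.config.classifier_on_sample and rng is not None) \
            else mu_u
        ce = ce + cross_entropy(cond[:, k], classify_condition(clf_in, state, k))
        gl = gl + group_lasso(state.params[f"enc_u{k}.w1"])
        zm = z_u if (state.config.mmd_on_sample or rng is None) else mu_u
        other = np.delete(np.arange(state.n_condition_types), k)
        ext = np.column_stack([keys[:, 0], cond[:, other]]) \
            if len(other) else keys[:, :1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mmd_u = mmd_u + mmd_unshared(zm, cond[:, k], ext, min_group)

    zm_s = z_s if (state.config.mmd_on_sample or rng is None) else mu_s
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mmd_s = mmd_shared(zm_s, keys, min_group)

    mu_nb, theta = decode(z_s, z_us, batch_factors, state, lib, rng)
    # reconstruction is reported per gene (mean over genes and cells) so the
    # recommended loss weights keep their intended relative strength
    recon = nb_log_likelihood(counts, mu_nb, theta, lgamma_x1).mean() \
        * (1.0 / counts.shape[1])
    return {"reconstruction": recon, "kl_shared": kl_s, "kl_unshared": kl_u,
            "mmd_shared": mmd_s, "mmd_unshared": mmd_u, "cross_entropy": ce,
            "group_lasso": gl}


def total_loss(counts: np.ndarray, batch_factors: np.ndarray,
               condition_codes: np.ndarray, state: ModelState,
               weights: LossWeights, library: np.ndarray | None = None,
               rng: np.random.Generator | None = None,
               min_group: int = 1) -> LossBreakdown:
    """Weighted objective over a batch of cells, as plain floats."""
    t = compute_losses(counts, batch_factors, condition_codes, state, weights,
                       library, rng, min_group)
    return LossBreakdown.combine(
        t["reconstruction"].item(), t["kl_shared"].item(),
        t["kl_unshared"].item(), t["mmd_shared"].item(),
        t["mmd_unshared"].item(), t["cross_entropy"].item(),
        t["group_lasso"].item(), weights)
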