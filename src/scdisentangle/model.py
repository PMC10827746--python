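"""Encoder/decoder/classifier/prior parameterization and the NB likelihood.

The generative model: each cell's raw counts x follow a negative binomial
whose mean is produced by a decoder from three groups of latent factors —

* ``z_s`` (dim ``d_s``, default 8): shared biological factors capturing cell
  identity, encoded from (preprocessed counts, one-hot batch factor);
* ``z_u[k]`` (dim ``d_u``, default 2, one block per condition type k):
  condition-driven factors, encoded from preprocessed counts only;
* ``b``: the cell's one-hot batch factor, passed through unchanged.

Encoders consume ``log1p`` of library-size-normalized counts (scaled to the
training-set median depth); the NB likelihood is evaluated on the raw
counts, with each cell's observed library size entering the decoder as a
fixed scale on the softmax-normalized mean signal.  Dispersion is gene-wise
(one value per gene shared across cells), parameterized through softplus
with a small positive floor.

Each unshared encoder's first-layer weight matrix ``W`` doubles as a gene
relevance map: the l2 norm of the column attached to gene i is that gene's
condition-association score (group-lasso regularization in the objective
drives irrelevant columns toward zero).

A per-condition-label Gaussian prior ``N(mu_c, sigma_c^2 I)`` with learnable
``mu_c`` and scalar ``sigma_c`` acts on each ``z_u`` block, and a linear
classifier on ``z_u`` predicts the cell's condition label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

HIDDEN = 128
DROPOUT = 0.2
LOGVAR_CLAMP = 10.0
THETA_FLOOR = 1e-4


@dataclass
class ModelConfig:
    d_s: int = 8
    d_u: int = 2
    hidden: int = HIDDEN
    dropout: float = DROPOUT
    batch_norm: bool = True             # batch-normalize hidden blocks
    classifier_on_sample: bool = True   # classify sampled z_u (vs posterior mean)
    mmd_on_sample: bool = True          # MMD on sampled latents (vs posterior means)


def _linear(rng: np.random.Generator, n_in: int, n_out: int,
            gain: float = 2.0) -> tuple[Tensor, Tensor]:
    w = rng.normal(0.0, np.sqrt(gain / n_in), size=(n_in, n_out))
    return Tensor(w, requires_grad=True), Tensor(np.zeros(n_out), requires_grad=True)


@dataclass
class ModelState:
    """All trainable parameters plus the bookkeeping needed for inference.

    Parameters are grouped into named partitions so the alternating training
    scheme can update one partition while leaving the other bit-identical.
    """

    config: ModelConfig
    n_genes: int
    n_batches: int
    n_labels: list[int]                 # C_k per condition type
    batch_levels: list[str]
    condition_types: list[str]
    condition_levels: list[list[str]]
    gene_ids: list[str]
    median_library: float
    params: dict[str, Tensor] = field(default_factory=dict)
    # batch-norm running statistics (non-trainable), keyed like params
    buffers: dict[str, np.ndarray] = field(default_factory=dict)
    # per-gene mean/sd of the log-scaled input on the training set
    gene_log_mean: np.ndarray | None = None
    gene_log_std: np.ndarray | None = None
    # per type k, per label c: mean unshared posterior mean over training cells
    label_latent_means: list[np.ndarray] | None = None

    @classmethod
    def initialize(cls, n_genes: int, n_batches: int, n_labels: list[int],
                   batch_levels: list[str], condition_types: list[str],
                   condition_levels: list[list[str]], gene_ids: list[str],
                   median_library: float, config: ModelConfig | None = None,
                   seed: int = 0) -> "ModelState":
        cfg = config or ModelConfig()
        rng = np.random.default_rng(seed)
        h, ds_, du = cfg.hidden, cfg.d_s, cfg.d_u
        p: dict[str, Tensor] = {}
        buf: dict[str, np.ndarray] = {}

        def bn(name: str) -> None:
            if not cfg.batch_norm:
                return
            p[f"{name}.g"] = Tensor(np.ones(h), requires_grad=True)
            p[f"{name}.beta"] = Tensor(np.zeros(h), requires_grad=True)
            buf[f"{name}.mean"] = np.zeros(h)
            buf[f"{name}.var"] = np.ones(h)

        # shared encoder: (genes + batch one-hot) -> 128 -> 128 -> heads
        p["enc_s.w1"], p["enc_s.b1"] = _linear(rng, n_genes + n_batches, h)
        p["enc_s.w2"], p["enc_s.b2"] = _linear(rng, h, h)
        bn("enc_s.bn1"); bn("enc_s.bn2")
        p["enc_s.wmu"], p["enc_s.bmu"] = _linear(rng, h, ds_, gain=1.0)
        p["enc_s.wlv"], p["enc_s.blv"] = _linear(rng, h, ds_, gain=1.0)
        for k, ck in enumerate(n_labels):
            p[f"enc_u{k}.w1"], p[f"enc_u{k}.b1"] = _linear(rng, n_genes, h)
            bn(f"enc_u{k}.bn1")
            p[f"enc_u{k}.wmu"], p[f"enc_u{k}.bmu"] = _linear(rng, h, du, gain=1.0)
            p[f"enc_u{k}.wlv"], p[f"enc_u{k}.blv"] = _linear(rng, h, du, gain=1.0)
            p[f"clf{k}.w"], p[f"clf{k}.b"] = _linear(rng, du, ck, gain=1.0)
            p[f"prior{k}.mu"] = Tensor(rng.normal(0.0, 1.0, size=(ck, du)),
                                       requires_grad=True)
            p[f"prior{k}.log_sigma"] = Tensor(np.zeros(ck), requires_grad=True)
        dec_in = ds_ + du * len(n_labels) + n_batches
        p["dec.w1"], p["dec.b1"] = _linear(rng, dec_in, h)
        p["dec.w2"], p["dec.b2"] = _linear(rng, h, h)
        bn("dec.bn1"); bn("dec.bn2")
        p["dec.wmean"], p["dec.bmean"] = _linear(rng, h, n_genes, gain=1.0)
        # gene-wise dispersion: input-independent head (learned per-gene bias)
        p["dec.btheta"] = Tensor(np.zeros(n_genes), requires_grad=True)
        return cls(config=cfg, n_genes=n_genes, n_batches=n_batches,
                   n_labels=list(n_labels), batch_levels=list(batch_levels),
                   condition_types=list(condition_types),
                   condition_levels=[list(l) for l in condition_levels],
                   gene_ids=list(gene_ids), median_library=float(median_library),
                   params=p, buffers=buf)

    # -- parameter partitions --------------------------------------------

    def partition(self, which: str) -> dict[str, Tensor]:
        """'shared' | 'decoder' | 'unshared' (encoders+classifiers+priors)."""
        if which == "shared":
            return {k: v for k, v in self.params.items() if k.startswith("enc_s.")}
        if which == "decoder":
            return {k: v for k, v in self.params.items() if k.startswith("dec.")}
        if which == "unshared":
            return {k: v for k, v in self.params.items()
                    if k.startswith(("enc_u", "clf", "prior"))}
        raise ValueError(f"unknown partition {which!r}")

    @property
    def n_condition_types(self) -> int:
        return len(self.n_labels)

    def unshared_first_layer(self, k: int) -> np.ndarray:
        """W of unshared encoder k, as (hidden x genes) with per-gene columns."""
        return self.params[f"enc_u{k}.w1"].data.T.copy()


# -- forward computations ---------------------------------------------------


def preprocess(counts: np.ndarray, median_library: float,
               library: np.ndarray | None = None) -> np.ndarray:
    """log1p of counts rescaled to the training median library size."""
    x = np.asarray(counts, dtype=np.float64)
    lib = x.sum(axis=-1, keepdims=True) if library is None else \
        np.asarray(library, dtype=np.float64).reshape(-1, 1)
    lib = np.maximum(lib, 1.0)
    return np.log1p(x / lib * median_library)


def model_input(state: "ModelState", counts: np.ndarray,
                library: np.ndarray | None = None) -> np.ndarray:
    """Encoder input: log-scaled counts, z-scored per gene.

    The per-gene statistics are those of the training set (persisted in the
    checkpoint); before `fit` has set them, the raw log-scaled values are
    returned unchanged.
    """
    x = preprocess(counts, state.median_library, library)
    if state.gene_log_mean is not None:
        x = (x - state.gene_log_mean) / np.maximum(state.gene_log_std, 1e-6)
    return x


BN_EPS = 1e-5
BN_MOMENTUM = 0.1


def _dropout_mask(rng: np.random.Generator | None, shape, rate: float):
    if rng is None or rate <= 0:
        return None
    return (rng.random(shape) >= rate) / (1.0 - rate)


def _hidden_block(x: Tensor, state: ModelState, wkey: str, bkey: str,
                  bn_name: str, rng: np.random.Generator | None) -> Tensor:
    """One hidden block: linear -> batch norm -> ReLU -> dropout.

    Training mode (`rng` given) normalizes by minibatch statistics and
    updates the running mean/variance; eval mode uses the running buffers,
    keeping every forward pass deterministic.
    """
    p, cfg = state.params, state.config
    h = x @ p[wkey] + p[bkey]
    if cfg.batch_norm:
        if rng is not None:
            m = h.mean(axis=0, keepdims=True)
            v = ((h - m) ** 2).mean(axis=0, keepdims=True)
            mom = BN_MOMENTUM
            state.buffers[f"{bn_name}.mean"] = (
                (1 - mom) * state.buffers[f"{bn_name}.mean"] + mom * m.data.ravel())
            state.buffers[f"{bn_name}.var"] = (
                (1 - mom) * state.buffers[f"{bn_name}.var"] + mom * v.data.ravel())
        else:
            m = Tensor(state.buffers[f"{bn_name}.mean"])
            v = Tensor(state.buffers[f"{bn_name}.var"])
        h = (h - m) / ad.sqrt(v + BN_EPS) * p[f"{bn_name}.g"] + p[f"{bn_name}.beta"]
    h = ad.relu(h)
    mask = _dropout_mask(rng, h.data.shape, cfg.dropout)
    if mask is not None:
        h = h * Tensor(mask)
    return h


def encode_shared(x: np.ndarray, b: np.ndarray, state: ModelState,
                  rng: np.random.Generator | None = None
                  ) -> tuple[Tensor, Tensor]:
    """Diagonal-Gaussian posterior (mean, log-variance) of z_s.

    `x` is the preprocessed expression (cells x genes); `b` the one-hot batch
    factors.  Pass `rng` to enable dropout (training mode).
    """
    x = np.atleast_2d(x)
    b = np.atleast_2d(b)
    if x.shape[1] != state.n_genes:
        raise ValueError(f"expected {state.n_genes} genes, got {x.shape[1]}")
    p = state.params
    inp = Tensor(np.concatenate([x, b], axis=1))
    h = _hidden_block(inp, state, "enc_s.w1", "enc_s.b1", "enc_s.bn1", rng)
    h = _hidden_block(h, state, "enc_s.w2", "enc_s.b2", "enc_s.bn2", rng)
    mu = h @ p["enc_s.wmu"] + p["enc_s.bmu"]
    lv = ad.clip(h @ p["enc_s.wlv"] + p["enc_s.blv"], -LOGVAR_CLAMP, LOGVAR_CLAMP)
    return mu, lv


def encode_unshared(x: np.ndarray, state: ModelState, k: int,
                    rng: np.random.Generator | None = None
                    ) -> tuple[Tensor, Tensor]:
    """Posterior of z_u for condition type k (batch factor NOT an input)."""
    if not 0 <= k < state.n_condition_types:
        raise ValueError(f"condition type index {k} out of range")
    x = np.atleast_2d(x)
    if x.shape[1] != state.n_genes:
        raise ValueError(f"expected {state.n_genes} genes, got {x.shape[1]}")
    p = state.params
    h = _hidden_block(Tensor(x), state, f"enc_u{k}.w1", f"enc_u{k}.b1",
                      f"enc_u{k}.bn1", rng)
    mu = h @ p[f"enc_u{k}.wmu"] + p[f"enc_u{k}.bmu"]
    lv = ad.clip(h @ p[f"enc_u{k}.wlv"] + p[f"enc_u{k}.blv"],
                 -LOGVAR_CLAMP, LOGVAR_CLAMP)
    return mu, lv


def sample_latent(mu: Tensor, log_var: Tensor,
                  rng: np.random.Generator) -> Tensor:
    """Reparameterized draw: mean + exp(log_var/2) * N(0, 1)."""
    eps = rng.standard_normal(mu.shape)
    return mu + ad.exp(log_var * 0.5) * Tensor(eps)


def decode(z_s: Tensor, z_us: list[Tensor], b: np.ndarray, state: ModelState,
           library: np.ndarray, rng: np.random.Generator | None = None
           ) -> tuple[Tensor, Tensor]:
    """NB output (mu, theta) for a batch of cells.

    The mean head is softmax-normalized over genes and scaled by each cell's
    library size, so per-cell predicted means sum to the library size
    exactly.  theta is gene-wise, softplus-activated with a positive floor.
    """
    for z in [z_s] + list(z_us):
        if not np.all(np.isfinite(z.data)):
            raise ValueError("non-finite latent factors passed to decoder")
    p = state.params
    b = np.atleast_2d(b)
    lib = np.asarray(library, dtype=np.float64).reshape(-1, 1)
    inp = ad.concat(list([z_s] + list(z_us)) + [Tensor(b)], axis=1)
    h = _hidden_block(inp, state, "dec.w1", "dec.b1", "dec.bn1", rng)
    h = _hidden_block(h, state, "dec.w2", "dec.b2", "dec.bn2", rng)
    logits = h @ p["dec.wmean"] + p["dec.bmean"]
    lse = ad.logsumexp(logits, axis=1, keepdims=True)
    pi = ad.exp(logits - lse)                       # rows sum to 1
    mu = pi * Tensor(lib)
    theta = ad.softplus(p["dec.btheta"]) + THETA_FLOOR
    return mu, theta


def nb_log_likelihood(x: np.ndarray, mu: Tensor, theta: Tensor,
                      lgamma_x1: np.ndarray | None = None) -> Tensor:
    """Sum over genes of the normalized NB log-pmf, per cell.

    log NB(x; mu, theta) = lgamma(x+theta) - lgamma(theta) - lgamma(x+1)
                           + theta*log(theta/(theta+mu)) + x*log(mu/(theta+mu))

    `lgamma_x1` may carry a precomputed lgamma(x+1) (it is constant in the
    parameters and x never changes across epochs).
    """
    from scipy.special import gammaln as _g

    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if lgamma_x1 is None:
        lgamma_x1 = _g(x + 1.0)
    tot = theta + mu
    ll = (ad.gammaln(theta + Tensor(x)) - ad.gammaln(theta) - Tensor(lgamma_x1)
          + theta * (ad.log(theta) - ad.log(tot))
          + Tensor(x) * (ad.log(mu) - ad.log(tot)))
    return ll.sum(axis=1)


def classify_condition(z_u: Tensor, state: ModelState, k: int) -> Tensor:
    """Linear (affine-only) logits over the C_k labels of condition type k."""
    p = state.params
    return z_u @ p[f"clf{k}.w"] + p[f"clf{k}.b"]


# -- checkpointing -----------------------------------------------------------

SCHEMA_VERSION = 1


def save_state(state: ModelState, path) -> None:
    """Write all parameters + categorical orders to a single HDF5 archive."""
    import json

    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        meta = {
            "n_genes": state.n_genes,
            "n_batches": state.n_batches,
            "n_labels": state.n_labels,
            "batch_levels": state.batch_levels,
            "condition_types": state.condition_types,
            "condition_levels": state.condition_levels,
            "gene_ids": state.gene_ids,
            "median_library": state.median_library,
            "config": vars(state.config),
        }
        f.attrs["meta"] = json.dumps(meta)
        g = f.create_group("params")
        for k, v in state.params.items():
            g.create_dataset(k, data=v.data)
        gb = f.create_group("buffers")
        for k, v in state.buffers.items():
            gb.create_dataset(k, data=v)
        if state.gene_log_mean is not None:
            f.create_dataset("gene_log_mean", data=state.gene_log_mean)
            f.create_dataset("gene_log_std", data=state.gene_log_std)
        if state.label_latent_means is not None:
            g2 = f.create_group("label_latent_means")
            for k, arr in enumerate(state.label_latent_means):
                g2.create_dataset(str(k), data=arr)


def load_state(path) -> ModelState:
    import json

    import h5py

    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        cfg = ModelConfig(**meta["config"])
        state = ModelState(
            config=cfg, n_genes=meta["n_genes"], n_batches=meta["n_batches"],
            n_labels=list(meta["n_labels"]), batch_levels=meta["batch_levels"],
            condition_types=meta["condition_types"],
            condition_levels=meta["condition_levels"], gene_ids=meta["gene_ids"],
            median_library=meta["median_library"],
        )
        state.params = {k: Tensor(v[...], requires_grad=True)
                        for k, v in f["params"].items()}
        if "buffers" in f:
            state.buffers = {k: v[...] for k, v in f["buffers"].items()}
        if "gene_log_mean" in f:
            state.gene_log_mean = f["gene_log_mean"][...]
            state.gene_log_std = f["gene_log_std"][...]
        if "label_latent_means" in f:
            g2 = f["label_latent_means"]
            state.label_latent_means = [g2[str(k)][...]
                                        for k in range(len(state.n_labels))]
    return state
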