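# scdisentangle

Disentangled conditional variational autoencoder for **multi-batch,
multi-condition single-cell RNA-seq count data**.

Single-cell experiments routinely span several technical batches *and*
several biological conditions (drug treatment, disease severity, age
group, ...). Standard integration removes batch effects but flattens the
condition effects along with them; differential-expression testing finds
condition genes but ignores batch structure; perturbation predictors
handle one condition type at a time. This package models all of it
jointly, for computational biologists who have a grid of count matrices
indexed by (batch, condition combination) — possibly with missing grid
cells — and want, from one model:

1. **batch integration that preserves condition effects** — a per-cell
   embedding split into shared-bio factors `z_s` (cell identity, free of
   batch and condition) and unshared-bio factors `z_u^(k)`, one block per
   condition type (condition-driven variation, free of batch);
2. **condition-associated key gene (CKG) detection** — a per-gene score
   `s_i = ||w_i||_2` from the group-lasso-regularized first layer of each
   unshared encoder;
3. **any-to-any perturbation prediction** — expression of given cells
   under a different condition combination and/or batch, via latent
   shifting vectors and batch-factor replacement.

## Model

Counts follow a negative binomial with softmax-normalized decoder mean
scaled by the observed library size and gene-wise dispersion:

    x | z_s, z_u, b  ~  NB(mu, theta),    mu = L * softmax(f(z_s, z_u^(1..K), b))

with diagonal-Gaussian posteriors from a shared encoder (input: expression
+ one-hot batch factor b) and one unshared encoder per condition type
(input: expression only). The objective combines the NB evidence lower
bound, a standard-normal prior on `z_s`, a learned Gaussian-mixture prior
(one component per condition label) on each `z_u`, a linear condition
classifier (cross-entropy), maximum-mean-discrepancy alignment of `z_s`
across all (batch x condition) groups and of each `z_u` across batches
within each label, and a group-lasso penalty on the unshared encoders'
first-layer gene columns:

    -E[log NB] + 1e-5 KL(z_s) + 1e-2 KL(z_u) + GL(W) + 1e-4 (MMD_s + MMD_u) + CE

Optimization alternates two Adam steps per minibatch: shared encoder +
decoder first, then unshared encoders + classifiers + priors + decoder.
See `docs/methods.md` for the full account, including the numerical
choices and their rationale. Everything runs on a small self-contained
reverse-mode autodiff engine over numpy (float64), so results are exactly
reproducible from a single seed on any machine with the scientific Python
stack — no GPU framework required.

A ground-truthed simulator (`scdisentangle.simulation`) generates
multi-batch multi-condition benchmarks: cell-type expression programs,
batch-specific gene-wise distortion, NB counts, and additive
U(eps-1, eps) condition shifts on designated CKGs, with a 9-dataset grid
crossing m_diff in {20, 50, 100} CKGs per type with eps in {2, 4, 8}.

## Worked example

```python
import numpy as np
from scdisentangle import (SimulationConfig, TrainConfig, simulate,
                           hold_out_matrices, fit, extract_latent,
                           ckg_scores, predict_perturbation,
                           PredictionRequest)
from scdisentangle.evaluation import ari, asw_batch, auprc

# 2 batches x (ctrl/stim) x (healthy/severe), 8 count matrices; the first
# 100 genes respond to treatment, the next 100 to severity (eps = 8)
cfg = SimulationConfig(n_cells_per_matrix=150, n_genes=420, m_diff=100,
                       epsilon=8.0, seed=1)
truth = simulate(cfg)
train, held = hold_out_matrices(truth, [("batch0", ("ctrl", "severe")),
                                        ("batch1", ("stim", "healthy"))])

state, log = fit(train, TrainConfig(max_epochs=170, seed=0))
lat = extract_latent(train, state)

print("ARI cell types | z_s :", ari(train.cell_types.to_numpy(), lat.z_s))
print("ASW-batch      | z_s :", asw_batch(lat.z_s, train.batches.to_numpy(),
                                          train.cell_types.to_numpy()))
for k, col in enumerate(train.conditions.columns):
    labels = train.conditions[col].to_numpy()
    print(f"ARI {col:10s}| z_u :", ari(labels, lat.z_u[k], n_clusters=2))

sc = ckg_scores(state)
print("AUPRC treatment CKGs :", auprc(sc.scores[0], truth.ckg_sets[0]))

# predict 50 cells as stim/severe cells of batch1
pred = predict_perturbation(train.subset(np.arange(50)), state,
                            PredictionRequest(
                                target_labels={"treatment": "stim",
                                               "severity": "severe"},
                                target_batch="batch1"))
print("predicted matrix shape:", pred.shape)
```

Output of this exact script (seeds as shown; about five minutes on one
CPU core):

```
ARI cell types | z_s : 1.0
ASW-batch      | z_s : 0.8770784704670014
ARI treatment | z_u : 0.9955555500808075
ARI severity  | z_u : 0.9822815270339881
AUPRC treatment CKGs : 0.2563221519197513
predicted matrix shape: (50, 420)
```

`z_s` clusters exactly by cell type with batches well mixed (ASW-batch
0.88 on a 0-1 scale, 1 = perfect mixing); each `z_u` block clusters by its
own condition label almost perfectly even though two of the eight
(batch, condition) matrices were never seen in training — at the full
benchmark size (~500 cells per matrix, `scripts/acceptance.py`) the
condition ARI reaches 0.998. CKG ranking is the noisiest of the three
outputs at this many (100 per type) condition genes; see the known
limitations in `docs/methods.md`. The predicted matrix contains denoised
expression for the 50 input cells under the requested target state, at
each cell's own sequencing depth.

A `scdisentangle` console command wraps the same workflow
(`simulate`, `train`, `predict`, `ckg`, `evaluate`); every run writes a
YAML echo of its resolved configuration for reproducibility.

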