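"""Metrics and baselines for benchmarking on ground-truthed data.

Disentanglement is scored by ARI (k-means on an embedding vs. reference
labels) and ASW-batch (silhouette on batch labels within biological groups,
mapped to [0, 1] by 1 - |s|; 1 = perfectly mixed batches).  Gene-ranking
accuracy uses AUPRC and early precision against the true CKG set, with a
Wilcoxon rank-sum baseline for comparison.  Expression predictions are
scored by MSE / Pearson / R^2 on library-size-normalized counts, either
cell-wise (when a one-to-one correspondence exists) or between per-cell-type
centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, average_precision_score
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

from .data import MultiConditionDataset


@dataclass
class EvaluationReport:
    """Tidy collection of named scalar metrics with their grouping keys."""

    rows: list[dict] = field(default_factory=list)

    def add(self, metric: str, value: float, **keys) -> None:
        self.rows.append({"metric": metric, "value": float(value), **keys})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def value(self, metric: str, **keys) -> float:
        for r in self.rows:
            if r["metric"] == metric and all(r.get(k) == v for k, v in keys.items()):
                return r["value"]
        raise KeyError(f"no row for {metric} with {keys}")


# -- clustering / mixing ----------------------------------------------------


def ari(true_labels, embedding, n_clusters: int | None = None,
        seed: int = 0) -> float:
    """Adjusted Rand index between seeded k-means clusters and true labels."""
    true_labels = np.asarray(true_labels)
    k = n_clusters or len(np.unique(true_labels))
    if k < 2:
        raise ValueError("need at least 2 clusters")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    pred = km.fit_predict(np.asarray(embedding))
    return float(adjusted_rand_score(true_labels, pred))


def asw_batch(embedding, batch_labels, group_labels) -> float:
    """Batch-mixing score in [0, 1]; higher = batches better mixed.

    Within each biological group, the silhouette width of each cell with its
    BATCH as the label is computed and mapped to 1 - |s|; scores are
    averaged within groups, then across groups.  Groups containing a single
    batch are skipped with a warning.
    """
    embedding = np.asarray(embedding)
    batch_labels = np.asarray(batch_labels)
    group_labels = np.asarray(group_labels)
    per_group = []
    for grp in np.unique(group_labels):
        sel = group_labels == grp
        if len(np.unique(batch_labels[sel])) < 2:
            warnings.warn(f"group {grp!r} has a single batch; skipped")
            continue
        s = silhouette_samples(embedding[sel], batch_labels[sel])
        per_group.append(np.mean(1.0 - np.abs(s)))
    if not per_group:
        raise ValueError("no group contains more than one batch")
    return float(np.mean(per_group))


# -- gene-ranking -----------------------------------------------------------


def auprc(scores, truth_set) -> float:
    """Area under the precision-recall curve of a gene ranking.

    Step-wise interpolation over score thresholds; tied scores share a
    threshold.  With all-equal scores the area degenerates to the
    prevalence of true genes (a warning is emitted).
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.zeros(len(scores), dtype=int)
    y[np.asarray(list(truth_set), dtype=int)] = 1
    if y.sum() == 0:
        raise ValueError("truth set is empty")
    if np.all(scores == scores[0]):
        warnings.warn("all scores equal; AUPRC equals prevalence")
        return float(y.mean())
    return float(average_precision_score(y, scores))


def early_precision(scores, truth_set) -> float:
    """Precision among the top-|truth| ranked genes (ties by gene order)."""
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(list(truth_set), dtype=int)
    k = len(truth)
    top = np.argsort(-scores, kind="stable")[:k]
    return float(len(np.intersect1d(top, truth)) / k)


def wilcoxon_ckg_baseline(ds: MultiConditionDataset, k: int) -> np.ndarray:
    """Rank-sum differential-expression baseline for CKG scoring.

    Per gene: two-sided Wilcoxon rank-sum p-value between the label groups
    of condition type k on library-size-normalized expression (min p over
    label pairs when there are more than two labels), Benjamini-Hochberg
    corrected, then mapped to scores 1 - p / max(p) in [0, 1].
    """
    codes = ds.condition_codes[:, k]
    labels = np.unique(codes)
    if len(labels) < 2:
        raise ValueError("need >= 2 labels for the rank-sum baseline")
    lib = np.maximum(ds.library_sizes(), 1.0)
    x = ds.counts / lib[:, None] * np.median(lib)
    pvals = np.ones(ds.n_genes)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            xa, xb = x[codes == a], x[codes == b]
            with np.errstate(all="ignore"):
                stat_p = stats.ranksums(xa, xb, axis=0).pvalue
            stat_p = np.where(np.isnan(stat_p), 1.0, stat_p)
            # constant genes: identical samples -> no evidence
            const = (xa.std(axis=0) == 0) & (xb.std(axis=0) == 0) & \
                    (np.abs(xa.mean(axis=0) - xb.mean(axis=0)) < 1e-12)
            stat_p = np.where(const, 1.0, stat_p)
            pvals = np.minimum(pvals, stat_p)
    padj = multipletests(pvals, method="fdr_bh")[1]
    return 1.0 - padj / padj.max()


# -- expression-prediction accuracy ----------------------------------------


def _normalize(x: np.ndarray) -> np.ndarray:
    lib = np.maximum(x.sum(axis=1, keepdims=True), 1e-12)
    return x / lib


def _triplet(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    mse = float(np.mean((a - b) ** 2))
    pr = float(np.corrcoef(a, b)[0, 1]) if a.std() > 0 and b.std() > 0 else 0.0
    ss_res = np.sum((a - b) ** 2)
    ss_tot = np.sum((a - a.mean()) ** 2)
    r2 = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else -np.inf
    return mse, pr, r2


def cell_metrics(pred_counts: np.ndarray, ref_counts: np.ndarray
                 ) -> tuple[float, float, float]:
    """Cell-level MSE / Pearson / R^2 for one-to-one matched cells."""
    a = _normalize(np.asarray(pred_counts, dtype=np.float64)).ravel()
    b = _normalize(np.asarray(ref_counts, dtype=np.float64)).ravel()
    return _triplet(b, a)


def centroid_metrics(pred_counts, ref_counts, pred_types, ref_types
                     ) -> pd.DataFrame:
    """Per-cell-type centroid MSE / Pearson / R^2 between two matrices.

    Both inputs are library-size normalized; the centroid of a cell type is
    the per-gene mean of its normalized expression.  Cell types present in
    only one input are skipped (recorded with NaN metrics).
    """
    pred = _normalize(np.asarray(pred_counts, dtype=np.float64))
    ref = _normalize(np.asarray(ref_counts, dtype=np.float64))
    pred_types = np.asarray(pred_types)
    ref_types = np.asarray(ref_types)
    rows = []
    for ct in np.unique(np.concatenate([pred_types, ref_types])):
        in_pred, in_ref = (pred_types == ct).any(), (ref_types == ct).any()
        if not (in_pred and in_ref):
            rows.append({"cell_type": ct, "mse": np.nan, "pearson": np.nan,
                         "r2": np.nan, "skipped": True})
            continue
        a = ref[ref_types == ct].mean(axis=0)
        p = pred[pred_types == ct].mean(axis=0)
        mse, pr, r2 = _triplet(a, p)
        rows.append({"cell_type": ct, "mse": mse, "pearson": pr, "r2": r2,
                     "skipped": False})
    return pd.DataFrame(rows)


# -- scenario suite ---------------------------------------------------------


@dataclass
class Scenario:
    """One prediction test: take cells of `input_matrix`, predict them under
    `target_matrix`, and score against the (denoised) cells actually
    observed there."""

    name: str
    input_matrix: tuple[str, tuple[str, ...]]    # (batch, condition combo)
    target_matrix: tuple[str, tuple[str, ...]]


def six_scenarios(batches: tuple[str, str],
                  combos: dict[str, tuple[str, str]],
                  source_combo: tuple[str, ...] | None = None
                  ) -> list[Scenario]:
    """The canonical 2-type, 2-batch design: {within, cross}-batch x
    {change type 1, change type 2, change both}."""
    types = list(combos.keys())
    src = source_combo or tuple(combos[t][0] for t in types)
    tgt1 = (combos[types[0]][1], src[1])
    tgt2 = (src[0], combos[types[1]][1])
    tgt_both = (combos[types[0]][1], combos[types[1]][1])
    out = []
    for bt, tag in [(batches[0], "within_batch"), (batches[1], "cross_batch")]:
        for combo, ctag in [(tgt1, types[0]), (tgt2, types[1]), (tgt_both, "both")]:
            out.append(Scenario(
                name=f"{tag}:{ctag}",
                input_matrix=(batches[0], src),
                target_matrix=(bt, combo)))
    return out


def run_scenario_suite(truth, state, scenarios: list[Scenario] | None = None,
                       seed: int = 0) -> EvaluationReport:
    """Disentanglement scores plus the prediction scenarios.

    For each scenario the gold standard is the denoised expression of the
    cells observed in the target matrix (the model's NB mean removes
    technical noise that a raw-count comparison would re-introduce);
    centroid metrics are computed per cell type.  Scenarios whose gold
    matrix has no cells are skipped and recorded.
    """
    from .tasks import PredictionRequest, denoise, extract_latent, predict_perturbation

    ds = truth.perturbed
    report = EvaluationReport()
    lat = extract_latent(ds, state)
    cell_types = ds.cell_types.to_numpy()
    batch = ds.batches.to_numpy()
    combo_key = np.array(["|".join(map(str, r))
                          for r in ds.conditions.to_numpy()])
    report.add("ari_cell_type", ari(cell_types, lat.z_s, seed=seed),
               space="shared")
    report.add("asw_batch",
               asw_batch(lat.z_s, batch, cell_types), space="shared")
    for k, tname in enumerate(state.condition_types):
        labels = ds.conditions[ds.conditions.columns[k]].to_numpy()
        report.add("ari_condition", ari(labels, lat.z_u[k], seed=seed),
                   space=f"unshared:{tname}")
        report.add("asw_batch", asw_batch(lat.z_u[k], batch, labels),
                   space=f"unshared:{tname}")

    if scenarios is None:
        combos = {t: tuple(lv) for t, lv in
                  zip(ds.condition_types,
                      [tuple(l) for l in ds.condition_levels])}
        scenarios = six_scenarios(tuple(ds.batch_levels[:2]), combos)

    for sc in scenarios:
        in_mask = truth.matrix_mask(*sc.input_matrix)
        gold_mask = truth.matrix_mask(*sc.target_matrix)
        if not in_mask.any() or not gold_mask.any():
            report.add("skipped", 1.0, scenario=sc.name)
            continue
        sub = ds.subset(in_mask)
        gold = ds.subset(gold_mask)
        tgt_batch, tgt_combo = sc.target_matrix
        req = PredictionRequest(
            target_labels=dict(zip(ds.condition_types, tgt_combo)),
            target_batch=tgt_batch)
        pred = predict_perturbation(sub, state, req)
        gold_dn = denoise(gold, state)
        cm = centroid_metrics(pred, gold_dn,
                              sub.cell_types.to_numpy(),
                              gold.cell_types.to_numpy())
        ok = cm[~cm["skipped"]]
        report.add("centroid_mse", ok["mse"].mean(), scenario=sc.name)
        report.add("centroid_pearson", ok["pearson"].mean(), scenario=sc.name)
        report.add("centroid_r2", ok["r2"].mean(), scenario=sc.name)
        # identity baseline: return the input unchanged
        bm = centroid_metrics(sub.counts, gold_dn,
                              sub.cell_types.to_numpy(),
                              gold.cell_types.to_numpy())
        report.add("centroid_mse_identity",
                   bm[~bm["skipped"]]["mse"].mean(), scenario=sc.name)
    return report
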