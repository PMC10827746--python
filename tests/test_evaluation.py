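"""Metric implementations against hand computations and brute force."""

import numpy as np
import pandas as pd
import pytest

from scdisentangle.data import MultiConditionDataset
from scdisentangle.evaluation import (ari, asw_batch, auprc, centroid_metrics,
                                      cell_metrics, early_precision,
                                      wilcoxon_ckg_baseline)


class TestARI:
    def test_perfect_clustering(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1, 2], 30)
        emb = labels[:, None] * 10.0 + rng.normal(scale=0.1, size=(90, 2))
        assert ari(labels, emb) == pytest.approx(1.0)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 3, size=10_000)
        emb = rng.normal(size=(10_000, 2))
        assert abs(ari(labels, emb)) < 0.02

    def test_hand_computed_contingency(self):
        # clusters {a,a,b}|{b,b,b} vs truth {x,x,x}|{y,y,y}:
        # pairs index formula on the 6-point contingency table
        from sklearn.metrics import adjusted_rand_score
        truth = [0, 0, 0, 1, 1, 1]
        pred = [0, 0, 1, 1, 1, 1]
        # brute-force ARI from pair counts
        from itertools import combinations
        same_t = {(i, j) for i, j in combinations(range(6), 2)
                  if truth[i] == truth[j]}
        same_p = {(i, j) for i, j in combinations(range(6), 2)
                  if pred[i] == pred[j]}
        n_pairs = 15
        a = len(same_t & same_p)
        b = len(same_t | same_p)
        exp = len(same_t) * len(same_p) / n_pairs
        expected = (a - exp) / (0.5 * (len(same_t) + len(same_p)) - exp)
        assert adjusted_rand_score(truth, pred) == pytest.approx(expected)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="2 clusters"):
            ari(np.zeros(5), np.zeros((5, 2)), n_clusters=1)


class TestASWBatch:
    def test_mixed_batches_score_near_one(self):
        rng = np.random.default_rng(2)
        emb = rng.normal(size=(2000, 2))
        batches = rng.integers(0, 2, 2000)
        groups = np.zeros(2000)
        assert asw_batch(emb, batches, groups) > 0.9

    def test_separated_batches_score_near_zero(self):
        rng = np.random.default_rng(3)
        batches = np.repeat([0, 1], 200)
        emb = batches[:, None] * 100.0 + rng.normal(size=(400, 2))
        assert asw_batch(emb, batches, np.zeros(400)) < 0.1

    def test_invariant_to_rotation(self):
        rng = np.random.default_rng(4)
        emb = rng.normal(size=(200, 2))
        batches = rng.integers(0, 2, 200)
        groups = rng.integers(0, 2, 200)
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        a = asw_batch(emb, batches, groups)
        b = asw_batch(emb @ rot.T + 7.0, batches, groups)
        assert a == pytest.approx(b, abs=1e-9)

    def test_single_batch_group_skipped_with_warning(self):
        rng = np.random.default_rng(5)
        emb = rng.normal(size=(60, 2))
        batches = np.r_[np.zeros(20), np.repeat([0, 1], 20)]
        groups = np.r_[np.zeros(20), np.ones(40)]
        with pytest.warns(UserWarning, match="single batch"):
            asw_batch(emb, batches, groups)


class TestGeneRanking:
    def test_perfect_ranking(self):
        scores = np.r_[np.ones(5), np.zeros(20)]
        assert auprc(scores, range(5)) == pytest.approx(1.0)
        assert early_precision(scores, range(5)) == pytest.approx(1.0)

    def test_all_equal_scores_return_prevalence(self):
        scores = np.full(500, 0.3)
        with pytest.warns(UserWarning, match="prevalence"):
            assert auprc(scores, range(20)) == pytest.approx(0.04)

    def test_brute_force_threshold_enumeration(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=30)
        truth = rng.choice(30, size=8, replace=False)
        y = np.isin(np.arange(30), truth).astype(int)
        # exhaustive step-wise area: sum over recall steps of precision
        order = np.argsort(-scores)
        tp = fp = 0
        area = 0.0
        prev_recall = 0.0
        for g in order:
            if y[g]:
                tp += 1
            else:
                fp += 1
            recall = tp / y.sum()
            precision = tp / (tp + fp)
            area += (recall - prev_recall) * precision
            prev_recall = recall
        assert auprc(scores, truth) == pytest.approx(area, abs=1e-12)

    def test_invariance_to_monotone_transform(self):
        rng = np.random.default_rng(7)
        scores = rng.random(50)
        truth = rng.choice(50, 10, replace=False)
        assert auprc(scores, truth) == pytest.approx(
            auprc(np.exp(3 * scores), truth))
        assert early_precision(scores, truth) == pytest.approx(
            early_precision(np.exp(3 * scores), truth))

    def test_early_precision_top_k_by_hand(self):
        scores = np.array([9.0, 8.0, 7.0, 1.0, 1.0, 0.5, 0.4, 3.0, 2.0, 6.0])
        truth = [0, 1, 9, 7]      # top-4 by score: 0, 1, 2, 9 -> 3 hits
        assert early_precision(scores, truth) == pytest.approx(0.75)
        assert early_precision(scores, [3, 4, 5, 6]) == 0.0


class TestWilcoxonBaseline:
    def _ds(self, counts, labels):
        return MultiConditionDataset(
            counts=counts, gene_ids=[f"g{i}" for i in range(counts.shape[1])],
            batches=pd.Series(["b"] * len(labels)),
            conditions=pd.DataFrame({"c": labels}))

    def test_shifted_gene_is_ranked_first(self):
        rng = np.random.default_rng(8)
        n = 60
        counts = rng.poisson(5.0, size=(n, 4))
        labels = ["a"] * (n // 2) + ["b"] * (n // 2)
        counts[n // 2:, 2] += 40
        scores = wilcoxon_ckg_baseline(self._ds(counts, labels), 0)
        assert np.argmax(scores) == 2
        assert scores.min() == 0.0        # the largest-p gene maps to 0
        assert np.all((scores >= 0) & (scores <= 1))

    def test_identical_groups_score_zero(self):
        counts = np.tile(np.arange(1, 7)[:, None], (1, 3))
        labels = ["a", "b"] * 3
        scores = wilcoxon_ckg_baseline(self._ds(counts, labels), 0)
        np.testing.assert_allclose(scores, 0.0)

    def test_matches_manual_rank_sum(self):
        # small two-group case checked against the exact statistic
        from scipy.stats import ranksums
        counts = np.array([[1, 10], [2, 12], [3, 9], [9, 1], [8, 2], [7, 3]])
        labels = ["a"] * 3 + ["b"] * 3
        lib = counts.sum(axis=1).astype(float)
        x = counts / lib[:, None] * np.median(lib)
        p = [ranksums(x[:3, g], x[3:, g]).pvalue for g in range(2)]
        from statsmodels.stats.multitest import multipletests
        padj = multipletests(np.minimum(p, 1.0), method="fdr_bh")[1]
        expected = 1 - padj / padj.max()
        got = wilcoxon_ckg_baseline(self._ds(counts, labels), 0)
        np.testing.assert_allclose(got, expected, rtol=1e-10)


class TestPredictionMetrics:
    def test_identical_matrices(self):
        rng = np.random.default_rng(9)
        x = rng.poisson(5.0, size=(20, 10)).astype(float)
        types = np.repeat(["a", "b"], 10)
        df = centroid_metrics(x, x, types, types)
        assert (df["mse"] == 0).all()
        np.testing.assert_allclose(df["pearson"], 1.0)
        np.testing.assert_allclose(df["r2"], 1.0)

    def test_constant_offset_keeps_pearson(self):
        rng = np.random.default_rng(10)
        ref = rng.random((1, 10)) + 0.5
        ref /= ref.sum()
        # construct normalized vectors directly via cell_metrics internals
        a = ref.ravel()
        offset = 0.01
        b = a + offset
        from scdisentangle.evaluation import _triplet
        mse, pr, r2 = _triplet(a, b)
        assert pr == pytest.approx(1.0)
        assert mse == pytest.approx(offset**2)
        assert r2 < 1.0

    def test_two_type_hand_computed_centroids(self):
        pred = np.array([[2.0, 2.0], [4.0, 4.0], [8.0, 0.0]])
        ref = np.array([[1.0, 3.0], [0.0, 4.0]])
        pt = np.array(["a", "a", "b"])
        rt = np.array(["a", "b"])
        df = centroid_metrics(pred, ref, pt, rt).set_index("cell_type")
        # normalized pred centroid for a: mean([.5,.5],[.5,.5]) = [.5,.5]
        # normalized ref centroid for a: [.25,.75]
        assert df.loc["a", "mse"] == pytest.approx(
            np.mean([(0.5 - 0.25) ** 2, (0.5 - 0.75) ** 2]))
        # type b: pred [1,0], ref [0,1]
        assert df.loc["b", "mse"] == pytest.approx(1.0)

    def test_type_in_one_input_is_skipped(self):
        df = centroid_metrics(np.ones((2, 3)), np.ones((2, 3)),
                              np.array(["a", "c"]), np.array(["a", "b"]))
        assert set(df[df["skipped"]]["cell_type"]) == {"b", "c"}

    def test_cell_level_variant(self):
        rng = np.random.default_rng(11)
        x = rng.poisson(10.0, size=(5, 8)).astype(float) + 1
        mse, pr, r2 = cell_metrics(x, x)
        assert mse == 0 and pr == pytest.approx(1.0) and r2 == pytest.approx(1.0)
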