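"""Objective components against closed forms, Monte Carlo, and brute force."""

import numpy as np
import pytest

from scdisentangle.autodiff import Tensor
from scdisentangle.losses import (LossBreakdown, LossWeights, cross_entropy,
                                  group_lasso, kl_gaussian_prior,
                                  kl_standard_normal, mmd, mmd_shared,
                                  mmd_unshared)
from scdisentangle.losses import MMD_BANDWIDTH_SCALES, _median_bandwidth


class TestKLStandardNormal:
    def test_zero_at_prior(self):
        kl = kl_standard_normal(Tensor(np.zeros((1, 4))), Tensor(np.zeros((1, 4))))
        np.testing.assert_allclose(kl.data, 0.0, atol=1e-15)

    def test_mean_shift_closed_form(self):
        # m=(1,1), s=1: KL = ||m||^2 / 2 = 1
        kl = kl_standard_normal(Tensor(np.ones((1, 2))), Tensor(np.zeros((1, 2))))
        np.testing.assert_allclose(kl.data, 1.0, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_monte_carlo(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=3)
        lv = rng.normal(scale=0.5, size=3)
        closed = kl_standard_normal(Tensor(m[None]), Tensor(lv[None])).item()
        n = 1_000_000
        z = m + np.exp(lv / 2) * rng.standard_normal((n, 3))
        log_q = -0.5 * (((z - m) ** 2) / np.exp(lv) + lv + np.log(2 * np.pi)).sum(1)
        log_p = -0.5 * (z**2 + np.log(2 * np.pi)).sum(1)
        diffs = log_q - log_p
        se = diffs.std() / np.sqrt(n)
        assert abs(closed - diffs.mean()) < 3 * se


class TestKLGaussianPrior:
    def test_zero_when_posterior_equals_component(self):
        pm = Tensor(np.array([[0.5, -1.0], [2.0, 2.0]]))
        pls = Tensor(np.log(np.array([0.7, 1.3])))
        kl = kl_gaussian_prior(
            Tensor(np.array([[2.0, 2.0]])),
            Tensor(np.full((1, 2), 2 * np.log(1.3))),
            np.array([1]), pm, pls)
        np.testing.assert_allclose(kl.data, 0.0, atol=1e-12)

    def test_mean_shift_closed_form(self):
        # m = mu_c + delta*e1, s = sigma_c: KL = delta^2 / (2 sigma_c^2)
        delta, sigma = 0.8, 1.7
        pm = Tensor(np.zeros((1, 2)))
        pls = Tensor(np.array([np.log(sigma)]))
        kl = kl_gaussian_prior(
            Tensor(np.array([[delta, 0.0]])),
            Tensor(np.full((1, 2), 2 * np.log(sigma))),
            np.array([0]), pm, pls)
        np.testing.assert_allclose(kl.data, delta**2 / (2 * sigma**2), rtol=1e-12)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(9)
        m, lv = rng.normal(size=2), rng.normal(scale=0.4, size=2)
        pmu, psig = rng.normal(size=2), 1.4
        closed = kl_gaussian_prior(
            Tensor(m[None]), Tensor(lv[None]), np.array([0]),
            Tensor(pmu[None]), Tensor(np.array([np.log(psig)]))).item()
        n = 1_000_000
        z = m + np.exp(lv / 2) * rng.standard_normal((n, 2))
        log_q = -0.5 * (((z - m) ** 2) / np.exp(lv) + lv + np.log(2 * np.pi)).sum(1)
        log_p = -0.5 * (((z - pmu) ** 2) / psig**2
                        + 2 * np.log(psig) + np.log(2 * np.pi)).sum(1)
        diffs = log_q - log_p
        assert abs(closed - diffs.mean()) < 3 * diffs.std() / np.sqrt(n)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            kl_gaussian_prior(Tensor(np.zeros((1, 2))), Tensor(np.zeros((1, 2))),
                              np.array([5]), Tensor(np.zeros((2, 2))),
                              Tensor(np.zeros(2)))


class TestMMD:
    def test_identical_samples_give_zero(self):
        a = np.random.default_rng(0).normal(size=(10, 3))
        np.testing.assert_allclose(mmd(a, a.copy()).data, 0.0, atol=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(8, 2)), rng.normal(size=(5, 2))
        np.testing.assert_allclose(mmd(a, b).data, mmd(b, a).data, rtol=1e-12)

    def test_two_point_brute_force(self):
        a = np.array([[0.0, 0.0], [1.0, 0.0]])
        b = np.array([[0.0, 1.0], [2.0, 2.0]])
        pooled = np.vstack([a, b])
        d = np.sqrt(((pooled[:, None] - pooled[None]) ** 2).sum(-1))
        med = np.median(d[np.triu_indices(4, 1)])

        def ksum(x, y):
            tot = 0.0
            for s in MMD_BANDWIDTH_SCALES:
                h = med * s
                for xi in x:
                    for yi in y:
                        tot += np.exp(-((xi - yi) ** 2).sum() / (2 * h * h))
            return tot / (len(x) * len(y))

        expected = ksum(a, a) + ksum(b, b) - 2 * ksum(a, b)
        np.testing.assert_allclose(mmd(a, b).data, expected, rtol=1e-10)

    def test_vanishes_with_sample_size_under_null(self):
        rng = np.random.default_rng(2)
        vals = []
        for n in (50, 500, 2000):
            a, b = rng.normal(size=(n, 2)), rng.normal(size=(n, 2))
            vals.append(mmd(a, b).item())
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 5e-3

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mmd(np.zeros((0, 2)), np.zeros((3, 2)))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimensionality"):
            mmd(np.zeros((2, 2)), np.zeros((3, 4)))


class TestGroupedMMD:
    def test_two_groups_reduce_to_direct_call(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(20, 2))
        keys = np.repeat([[0], [1]], [12, 8], axis=0)
        direct = mmd(z[:12], z[12:]).item()
        np.testing.assert_allclose(
            mmd_shared(Tensor(z), keys).item(), direct, rtol=1e-12)

    def test_three_identical_groups_give_zero(self):
        z = np.tile(np.random.default_rng(4).normal(size=(5, 2)), (3, 1))
        keys = np.repeat([[0], [1], [2]], 5, axis=0)
        np.testing.assert_allclose(mmd_shared(Tensor(z), keys).item(), 0.0,
                                   atol=1e-12)

    def test_reference_is_largest_group(self):
        rng = np.random.default_rng(5)
        z = Tensor(rng.normal(size=(30, 2)))
        keys = np.repeat([[0], [1], [2]], 10, axis=0)
        keys[:25] = keys[:25]  # equal sizes except make group 1 largest
        keys = np.repeat([[0], [1], [2]], [8, 14, 8], axis=0)
        ref = slice(8, 22)
        expected = (mmd(z.data[ref], z.data[:8]).item()
                    + mmd(z.data[ref], z.data[22:]).item())
        np.testing.assert_allclose(mmd_shared(z, keys).item(), expected,
                                   rtol=1e-12)

    def test_single_group_warns_and_returns_zero(self):
        z = Tensor(np.zeros((6, 2)))
        with pytest.warns(UserWarning, match="fewer than 2 groups"):
            assert mmd_shared(z, np.zeros((6, 1), dtype=int)).item() == 0.0

    def test_null_convergence_at_scale(self):
        rng = np.random.default_rng(6)
        z = Tensor(rng.normal(size=(2000, 2)))
        keys = rng.integers(0, 4, size=(2000, 1))
        assert mmd_shared(z, keys).item() < 0.02

    def test_unshared_single_batch_is_zero(self):
        rng = np.random.default_rng(7)
        z = Tensor(rng.normal(size=(20, 2)))
        labels = np.repeat([0, 1], 10)
        ext = np.zeros((20, 1), dtype=int)
        assert mmd_unshared(z, labels, ext).item() == 0.0

    def test_unshared_sums_within_labels_only(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=(40, 2))
        labels = np.repeat([0, 1], 20)
        ext = np.tile(np.repeat([[0], [1]], 10, axis=0), (2, 1))
        expected = (mmd(z[:10], z[10:20]).item()
                    + mmd(z[20:30], z[30:40]).item())
        np.testing.assert_allclose(
            mmd_unshared(Tensor(z), labels, ext).item(), expected, rtol=1e-12)

    def test_extended_batches_split_by_other_condition(self):
        # K=2 grouping for type-1 alignment: batch x type-2 label
        rng = np.random.default_rng(9)
        z = rng.normal(size=(40, 2))
        labels = np.zeros(40, dtype=int)          # one label of type 1
        batch = np.repeat([0, 1], 20)
        other = np.tile(np.repeat([0, 1], 10), 2)
        ext = np.column_stack([batch, other])     # 4 extended batches
        groups = [z[(batch == b) & (other == o)]
                  for b in (0, 1) for o in (0, 1)]
        expected = sum(mmd(groups[0], g).item() for g in groups[1:])
        np.testing.assert_allclose(
            mmd_unshared(Tensor(z), labels, ext).item(), expected, rtol=1e-12)


class TestGroupLassoAndCE:
    def test_identity_matrix_norm(self):
        assert group_lasso(Tensor(np.eye(5))).item() == pytest.approx(5.0)

    def test_zero_matrix(self):
        assert group_lasso(Tensor(np.zeros((4, 3)))).item() == 0.0

    def test_random_matches_column_norm_sum(self):
        w = np.random.default_rng(10).normal(size=(3, 5))
        np.testing.assert_allclose(group_lasso(Tensor(w)).item(),
                                   np.linalg.norm(w, axis=1).sum(), rtol=1e-12)

    def test_uniform_logits_give_log_c(self):
        logits = Tensor(np.zeros((4, 5)))
        np.testing.assert_allclose(
            cross_entropy(np.array([0, 1, 2, 3]), logits).item(),
            np.log(5.0), rtol=1e-12)

    def test_confident_logits_approach_zero(self):
        logits = np.full((3, 2), -50.0)
        labels = np.array([0, 1, 0])
        logits[np.arange(3), labels] = 50.0
        assert cross_entropy(labels, Tensor(logits)).item() < 1e-12

    def test_manual_two_by_three(self):
        logits = np.array([[1.0, 2.0, 0.5], [-1.0, 0.0, 3.0]])
        labels = np.array([1, 2])
        p1 = np.exp(2.0) / np.exp(logits[0]).sum()
        p2 = np.exp(3.0) / np.exp(logits[1]).sum()
        expected = -(np.log(p1) + np.log(p2)) / 2
        np.testing.assert_allclose(cross_entropy(labels, Tensor(logits)).item(),
                                   expected, rtol=1e-12)

    def test_label_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            cross_entropy(np.array([3]), Tensor(np.zeros((1, 2))))


class TestBreakdown:
    def test_weighted_recombination(self):
        w = LossWeights()
        bd = LossBreakdown.combine(-100.0, 2.0, 3.0, 0.1, 0.2, 0.5, 40.0, w)
        manual = (100.0 + w.lambda_kl1 * 2.0 + w.lambda_kl2 * 3.0
                  + w.lambda_gl * 40.0 + w.lambda_mmd * 0.3
                  + w.lambda_ce * 0.5)
        assert abs(bd.total - manual) / abs(manual) < 1e-6

    def test_zero_weights_leave_negative_reconstruction(self):
        w = LossWeights(0, 0, 0, 0, 0)
        bd = LossBreakdown.combine(-77.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, w)
        assert bd.total == 77.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            LossWeights(lambda_mmd=-1.0)


def test_median_bandwidth_positive_on_degenerate_sample():
    assert _median_bandwidth(np.zeros((5, 2))) == 1.0


class TestPropertyInvariants:
    """Randomized invariants of the objective components."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _posteriors():
        from hypothesis import strategies as st
        from hypothesis.extra import numpy as hnp
        import numpy as _np
        shape = st.integers(1, 6).flatmap(
            lambda n: st.integers(1, 5).map(lambda d: (n, d)))
        return shape.flatmap(lambda s: st.tuples(
            hnp.arrays(_np.float64, s,
                       elements=st.floats(-5, 5, allow_nan=False)),
            hnp.arrays(_np.float64, s,
                       elements=st.floats(-3, 3, allow_nan=False))))

    @given(_posteriors())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_kl_terms_are_nonnegative(self, post):
        m, lv = post
        assert kl_standard_normal(Tensor(m), Tensor(lv)).item() >= -1e-12
        prior_mu = Tensor(np.zeros((1, m.shape[1])))
        prior_ls = Tensor(np.zeros(1))
        labels = np.zeros(m.shape[0], dtype=int)
        assert kl_gaussian_prior(Tensor(m), Tensor(lv), labels,
                                 prior_mu, prior_ls).item() >= -1e-12

    @given(_posteriors())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mmd_nonnegative_and_symmetric(self, post):
        a, _ = post
        b = a[::-1] + 1.0
        v1, v2 = mmd(a, b).item(), mmd(b, a).item()
        assert v1 >= -1e-10
        assert v1 == pytest.approx(v2, abs=1e-12)
        # multiset identity gives zero
        assert abs(mmd(a, a.copy()).item()) < 1e-10
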