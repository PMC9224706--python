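"""Wilcoxon, ROC/AUC, operating points — checked against exhaustive oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from evir.biomarker_stats import (
    closest_topleft_threshold,
    roc_auc,
    wilcoxon_rank_sum,
    youden_threshold,
)


def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exhaustive permutation enumeration of the two-sided rank-sum p-value.

    Enumerates all C(n_x+n_y, n_x) assignments of the pooled observations
    to the first sample and computes p = min(1, 2·min(P(U≤u), P(U≥u))).
    """
    pooled = np.concatenate([x, y])
    n = pooled.size
    nx = x.size
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = [
        ranks[list(idx)].sum() - nx * (nx + 1) / 2
        for idx in itertools.combinations(range(n), nx)
    ]
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_textbook_example(self):
        # {1,2} vs {3,4}: the most extreme of C(4,2)=6 rank splits on each side
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_samples_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("nx,ny", [(n, m) for n in range(1, 7) for m in range(1, 7)])
    def test_exact_branch_matches_enumeration(self, nx, ny):
        rng = np.random.default_rng(nx * 10 + ny)
        x = rng.normal(size=nx)
        y = rng.normal(0.8, 1.0, size=ny)
        res = wilcoxon_rank_sum(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)

    def test_large_or_tied_samples_use_normal_approximation(self):
        rng = np.random.default_rng(1)
        res = wilcoxon_rank_sum(rng.normal(size=15), rng.normal(size=15))
        assert res.method == "normal-approximation"
        res_tied = wilcoxon_rank_sum([1.0, 2.0, 2.0], [2.0, 3.0])
        assert res_tied.method == "normal-approximation"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=5), rng.normal(1, 1, size=6)
        assert wilcoxon_rank_sum(x, y).p_value == pytest.approx(
            wilcoxon_rank_sum(y, x).p_value, abs=1e-12
        )


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0

    def test_constant_scores_uninformative(self):
        r = roc_auc([5.0] * 6, [0, 0, 0, 1, 1, 1])
        assert r.auc == pytest.approx(0.5)

    def test_pair_counting_example(self):
        # cases {0.9, 0.25}, controls {0.3, 0.2}: 3 of 4 pairs concordant
        r = roc_auc([0.9, 0.25, 0.3, 0.2], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.75)

    @given(st.integers(0, 2**32 - 1))
    def test_auc_equals_mann_whitney_identity(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(3, 15, size=2)
        scores = np.round(rng.normal(size=n1 + n0), 1)  # coarse → ties occur
        labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert roc_auc(scores, labels).auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    def test_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(2.0 * scores), labels)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        np.testing.assert_allclose(a.sensitivity, b.sensitivity, atol=1e-12)

    def test_curve_runs_from_origin_to_corner(self):
        rng = np.random.default_rng(3)
        r = roc_auc(rng.normal(size=30), rng.integers(0, 2, 30))
        assert r.sensitivity[0] == 0.0 and r.specificity[0] == 1.0
        assert r.sensitivity[-1] == 1.0 and r.specificity[-1] == 0.0

    def test_orientation_flips_reversed_marker(self):
        scores = [3.0, 2.9, 1.0, 1.1]  # controls high
        labels = [0, 0, 1, 1]
        plain = roc_auc(scores, labels)
        oriented = roc_auc(scores, labels, orient=True)
        assert plain.auc < 0.5 and oriented.auc > 0.5 and oriented.flipped

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_delong_ci_matches_independent_reference(self):
        """Frozen oracle: 95% DeLong CI computed for this exact dataset with
        the pROC R package (ci.auc, method='delong'): 0.6869–0.9916."""
        ctrl = [0.3047, -1.04, 0.7505, 0.9406, -1.951, -1.3022,
                0.1278, -0.3162, -0.0168, -0.853, 0.8794, 0.7778]
        case = [1.066, 2.1272, 1.4675, 0.1407, 1.3688, 0.0411, 1.8785,
                0.9501, 0.8151, 0.3191, 2.2225, 0.8455, 0.5717, 0.6479]
        scores = np.r_[ctrl, case]
        labels = np.r_[np.zeros(len(ctrl), int), np.ones(len(case), int)]
        r = roc_auc(scores, labels, ci_method="delong")
        assert r.auc == pytest.approx(0.8393, abs=1e-4)
        assert r.ci_low == pytest.approx(0.6869, abs=1e-4)
        assert r.ci_high == pytest.approx(0.9916, abs=1e-4)

    def test_bootstrap_ci_brackets_auc(self):
        rng = np.random.default_rng(4)
        scores = np.r_[rng.normal(0, 1, 15), rng.normal(1, 1, 15)]
        labels = np.r_[np.zeros(15, int), np.ones(15, int)]
        r = roc_auc(scores, labels, ci_method="bootstrap", rng=np.random.default_rng(0))
        assert r.ci_low <= r.auc <= r.ci_high
        assert 0.0 <= r.ci_low < r.ci_high <= 1.0


def brute_force_best(scores, labels, objective):
    """Scan every threshold in [−inf, each score, +inf] and return the best
    (sens, spec) under ``objective`` with ties toward higher sensitivity."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best_obj, best_sens, best_spec = -np.inf, -1.0, -1.0
    for t in np.concatenate([[-np.inf], np.unique(scores), [np.inf]]):
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        obj = objective(sens, spec)
        # numeric ties (within 1e-12) broken toward higher sensitivity
        if obj > best_obj + 1e-12 or (obj > best_obj - 1e-12 and sens > best_sens):
            best_obj, best_sens, best_spec = max(obj, best_obj), sens, spec
    return best_sens, best_spec


class TestOperatingPoints:
    def test_perfect_separation_gives_perfect_point(self):
        r = roc_auc([1, 2, 10, 11], [0, 0, 1, 1])
        op = youden_threshold(r)
        assert (op.sensitivity, op.specificity, op.youden_j) == (1.0, 1.0, 1.0)
        tl = closest_topleft_threshold(r)
        assert (tl.sensitivity, tl.specificity) == (1.0, 1.0)

    def test_uninformative_scores_give_zero_j(self):
        r = roc_auc([1.0] * 8, [0, 0, 0, 0, 1, 1, 1, 1])
        assert youden_threshold(r).youden_j == pytest.approx(0.0)

    @given(st.integers(0, 2**32 - 1))
    def test_youden_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=40), 1)
        labels = np.r_[np.ones(20, int), np.zeros(20, int)]
        scores[labels == 1] += 0.5
        r = roc_auc(scores, labels)
        op = youden_threshold(r)
        sens, spec = brute_force_best(scores, labels, lambda se, sp: se + sp - 1)
        assert (op.sensitivity, op.specificity) == pytest.approx((sens, spec), abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    def test_topleft_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=40), 1)
        labels = np.r_[np.ones(20, int), np.zeros(20, int)]
        scores[labels == 1] += 0.5
        r = roc_auc(scores, labels)
        op = closest_topleft_threshold(r)
        sens, spec = brute_force_best(
            scores, labels, lambda se, sp: -((1 - se) ** 2 + (1 - sp) ** 2)
        )
        assert (op.sensitivity, op.specificity) == pytest.approx((sens, spec), abs=1e-12)

    def test_symmetric_binormal_points_coincide(self):
        # equal-variance binormal with symmetric means: both criteria pick
        # the central threshold, so the operating points (nearly) coincide
        rng = np.random.default_rng(5)
        ctrl = rng.normal(-1.0, 1.0, 500)
        case = rng.normal(1.0, 1.0, 500)
        scores = np.r_[ctrl, case]
        labels = np.r_[np.zeros(500, int), np.ones(500, int)]
        r = roc_auc(scores, labels)
        y = youden_threshold(r)
        t = closest_topleft_threshold(r)
        assert y.sensitivity == pytest.approx(t.sensitivity, abs=0.02)
        assert y.specificity == pytest.approx(t.specificity, abs=0.02)
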