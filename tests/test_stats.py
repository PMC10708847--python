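"""Correlation models, robust outlier detection, group comparison."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from betawatch.core import (
    ConstantInputError,
    EmptyGroupError,
    InsufficientDataError,
)
from betawatch.stats import (
    compare_groups,
    correlate,
    correlation_power,
    form_groups,
    skipped_outliers,
)


class TestCorrelate:
    def test_monotone_data_has_spearman_one(self):
        x = np.arange(10.0)
        y = np.exp(x)
        res = correlate(x, y, model="spearman", n_boot=50, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_skipped_equals_spearman_when_nothing_flagged(self, elliptical_cloud):
        x, y = elliptical_cloud
        sk = correlate(x, y, model="skipped", n_boot=50, seed=42)
        sp = correlate(x, y, model="spearman", n_boot=50, seed=42)
        assert sk.n_outliers == 0
        assert abs(sk.r - sp.r) < 1e-12
        assert abs(sk.p_value - sp.p_value) < 1e-12

    def test_pearson_sampling_bound(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(1000)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(1000)
        res = correlate(x, y, model="pearson", n_boot=50, seed=0)
        assert 0.45 <= res.r <= 0.55
        lo, hi = res.ci95
        assert lo <= res.r <= hi

    def test_constant_vector_rejected(self):
        with pytest.raises(ConstantInputError):
            correlate(np.ones(20), np.arange(20.0), model="pearson")

    def test_bootstrap_ci_brackets_estimate(self, elliptical_cloud):
        x, y = elliptical_cloud
        for model in ("pearson", "spearman", "skipped"):
            res = correlate(x, y, model=model, n_boot=400, seed=1)
            assert res.ci95[0] <= res.r <= res.ci95[1]
            assert -1 <= res.r <= 1
            assert 0 <= res.power <= 1

    def test_power_matches_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        for r, n in [(0.3, 34), (0.53, 29), (0.1, 100)]:
            ref = pingouin.power_corr(r=r, n=n, alternative="two-sided")
            assert correlation_power(r, n) == pytest.approx(ref, abs=1e-6)


class TestSkippedOutliers:
    def test_clean_cloud_flags_nothing(self, elliptical_cloud):
        x, y = elliptical_cloud
        assert len(skipped_outliers(x, y, seed=42)) == 0

    def test_single_gross_outlier_flagged_exactly(self, elliptical_cloud):
        x, y = elliptical_cloud
        x2, y2 = np.append(x, 10.0), np.append(y, -10.0)
        flagged = skipped_outliers(x2, y2, seed=42)
        assert flagged.tolist() == [100]

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            skipped_outliers(np.arange(5.0), np.arange(5.0))

    def test_matches_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        x = rng.standard_normal(100)
        y = 0.5 * x + 0.8 * rng.standard_normal(100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_ref, p_ref, out_ref = pingouin.correlation.skipped(x, y)
        mine = skipped_outliers(x, y, seed=42)
        assert mine.tolist() == np.flatnonzero(out_ref).tolist()
        res = correlate(x, y, model="skipped", n_boot=50, seed=42)
        assert res.r == pytest.approx(r_ref, abs=1e-12)

    def test_contamination_robustness(self):
        # 5% gross outliers barely move skipped r but wreck Pearson
        rng = np.random.default_rng(5)
        n = 200
        x = rng.standard_normal(n)
        y = 0.6 * x + 0.8 * rng.standard_normal(n)
        k = 10
        xc = np.concatenate([x, rng.uniform(5, 8, k)])
        yc = np.concatenate([y, rng.uniform(-8, -5, k)])
        r_p = correlate(x, y, model="pearson", n_boot=10, seed=1).r
        r_pc = correlate(xc, yc, model="pearson", n_boot=10, seed=1).r
        r_s = correlate(x, y, model="skipped", n_boot=10, seed=1).r
        r_sc = correlate(xc, yc, model="skipped", n_boot=10, seed=1).r
        assert abs(r_pc - r_p) > 0.2
        assert abs(r_sc - r_s) < 0.1


class TestFormGroups:
    def test_hand_worked_exclusion(self):
        scores = np.array([2.0, 3.0, 5.2, 7.0, 8.0])  # mean 5.04
        betas = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        ga = form_groups(scores, betas)
        assert ga.excluded_mid_idx.tolist() == [2]
        assert ga.worst_idx.tolist() == [0, 1]
        assert ga.best_idx.tolist() == [3, 4]

    def test_all_equal_scores_empty_groups(self):
        with pytest.raises(EmptyGroupError):
            form_groups(np.full(10, 5.0), np.arange(10.0))

    def test_percentile_trim_removes_extremes(self):
        rng = np.random.default_rng(7)
        n = 40
        betas = np.concatenate([rng.normal(0.5, 0.05, n - 2), [5.0, -5.0]])
        scores = np.concatenate([np.where(np.arange(n - 2) % 2 == 0, 8.0, 2.0),
                                 [8.0, 8.0]])
        ga = form_groups(scores, betas)
        assert {n - 2, n - 1} <= set(ga.trimmed_idx.tolist())
        assert not {n - 2, n - 1} & set(ga.best_idx.tolist())


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(8)
        g = rng.normal(0, 1, 15)
        res = compare_groups(g, g)
        assert res.p_value > 0.9
        assert not res.significant

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 20)
        b = rng.normal(2, 1, 20)  # 2 SD shift: power ~ 1
        res = compare_groups(a, b)
        assert res.significant
        assert res.p_value < 0.05
        assert res.medians[0] < res.medians[1]

    def test_u_statistic_matches_pair_counting(self):
        # exhaustive oracle on small untied groups
        rng = np.random.default_rng(10)
        for trial in range(5):
            a = rng.uniform(0, 1, 6)
            b = rng.uniform(0, 1, 7)
            res = compare_groups(a, b)
            if res.test_used != "mann_whitney":
                continue
            u_brute = sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)
            assert res.statistic == pytest.approx(u_brute)

    def test_too_small_group_raises(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(0.1, 5.0), shift=st.floats(-2.0, 2.0))
    def test_mann_whitney_invariant_under_monotone_transform(self, scale, shift):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 14)
        base = compare_groups(a, b)
        f = lambda v: np.exp(scale * v) + shift  # strictly increasing
        trans = compare_groups(f(a), f(b))
        if base.test_used == "mann_whitney" and trans.test_used == "mann_whitney":
            assert trans.p_value == pytest.approx(base.p_value, rel=1e-9)
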