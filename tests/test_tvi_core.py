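import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tvidex.errors import ValidationError
from tvidex.tvi_core import (
    SplineBasis,
    TviTester,
    bootstrap_pvalue,
    build_tvi_basis,
    fit_curve,
    tvi_statistic,
)


def segment_mean_rss(y, times, knot):
    """Independent degree-0 oracle: RSS around per-segment means."""
    y = np.asarray(y, float)
    t = np.asarray(times, float)
    rss = 0.0
    for mask in (t < knot, t >= knot):
        if mask.any():
            rss += float(((y[mask] - y[mask].mean()) ** 2).sum())
    return rss


def degree0_statistic_oracle(y, times, groups, knot):
    y = np.asarray(y, float)
    t = np.asarray(times, float)
    g = np.asarray(groups, dtype=object)
    rss_null = segment_mean_rss(y, t, knot)
    rss_alt = sum(segment_mean_rss(y[g == lab], t[g == lab], knot) for lab in set(g))
    return rss_null, rss_alt, (rss_null - rss_alt) / rss_alt


class TestBuildBasis:
    def test_median_followup_knot_is_14(self):
        times = [0, 0, 0, 10, 12, 14, 180, 190]  # median of the 5 positives = 14
        followup = sorted(t for t in times if t > 0)
        assert np.median(followup) == 14
        basis = build_tvi_basis(times)
        assert basis.knot_days == 14

    def test_degree0_partition_of_unity(self):
        basis = SplineBasis(knot_days=14.0, degree=0, domain=(0.0, 200.0))
        B = basis.design_matrix(np.linspace(0, 200, 41))
        assert B.shape[1] == 2
        np.testing.assert_allclose(B.sum(axis=1), 1.0)
        assert set(np.unique(B)) <= {0.0, 1.0}

    def test_degree1_partition_of_unity_nonnegative(self):
        basis = SplineBasis(knot_days=14.0, degree=1, domain=(0.0, 200.0))
        rng = np.random.default_rng(0)
        t = rng.uniform(0, 200, size=50)
        B = basis.design_matrix(t)
        assert B.shape == (50, 3)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(B >= 0)

    def test_dimension(self):
        assert SplineBasis(1.0, 0, (0.0, 2.0)).dimension == 2
        assert SplineBasis(1.0, 1, (0.0, 2.0)).dimension == 3

    def test_all_times_identical_error(self):
        with pytest.raises(ValidationError):
            build_tvi_basis([5.0, 5.0, 5.0])

    def test_knot_outside_range_error(self):
        with pytest.raises(ValidationError):
            build_tvi_basis([0.0, 1.0, 2.0], knot_policy="fixed", knot=5.0)

    def test_no_followup_times_error(self):
        with pytest.raises(ValidationError):
            build_tvi_basis([0.0, 0.0], knot_policy="median_followup")

    def test_fixed_policy_requires_knot(self):
        with pytest.raises(ValidationError):
            build_tvi_basis([0.0, 1.0, 2.0], knot_policy="fixed")


class TestFitCurve:
    def test_constant_y_zero_rss(self):
        basis = SplineBasis(10.0, 1, (0.0, 100.0))
        times = [0, 5, 20, 50, 100]
        fit = fit_curve([3.0] * 5, times, basis)
        np.testing.assert_allclose(fit.fitted_values, 3.0, atol=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        basis = SplineBasis(10.0, 1, (0.0, 100.0))
        times = rng.uniform(0, 100, size=30)
        y = rng.normal(size=30)
        fit = fit_curve(y, times, basis)
        X = basis.design_matrix(times)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        rss = float(((y - X @ beta) ** 2).sum())
        assert fit.rss == pytest.approx(rss, rel=1e-10)

    def test_two_distinct_times_rank_deficient_equals_per_time_means(self):
        # degree-1 basis on a two-timepoint design: RSS = per-time mean fit RSS
        basis = SplineBasis(90.0, 1, (0.0, 180.0))
        times = np.array([0.0, 0.0, 0.0, 180.0, 180.0])
        y = np.array([1.0, 2.0, 3.0, 10.0, 12.0])
        fit = fit_curve(y, times, basis)
        assert fit.rank < basis.dimension
        rss_oracle = ((y[:3] - 2.0) ** 2).sum() + ((y[3:] - 11.0) ** 2).sum()
        assert fit.rss == pytest.approx(rss_oracle, rel=1e-10)

    def test_empty_input_error(self):
        basis = SplineBasis(10.0, 1, (0.0, 100.0))
        with pytest.raises(ValidationError):
            fit_curve([], [], basis)


class TestStatistic:
    def test_identical_groups_give_zero(self):
        basis = SplineBasis(10.0, 1, (0.0, 100.0))
        times = [0, 5, 20, 50, 100] * 2
        y = [1.0, 2.0, 1.5, 3.0, 2.5] * 2
        groups = ["ISR"] * 5 + ["NO_ISR"] * 5
        t = tvi_statistic(y, times, groups, basis)
        assert t.statistic == pytest.approx(0.0, abs=1e-9)

    def test_worked_degree0_example(self):
        # segment means: pooled pre {1,3,1,3} -> RSS 4, post {5,7,1,3} -> RSS 20;
        # per-group segments each contribute 2 -> RSS_alt 8; T = (24-8)/8 = 2
        basis = SplineBasis(10.0, 0, (0.0, 20.0))
        times = [1, 1, 20, 20, 1, 1, 20, 20]
        y = [1, 3, 5, 7, 1, 3, 1, 3]
        groups = ["ISR"] * 4 + ["NO_ISR"] * 4
        t = tvi_statistic(y, times, groups, basis)
        assert t.rss_null == pytest.approx(24.0, rel=1e-12)
        assert t.rss_alt == pytest.approx(8.0, rel=1e-12)
        assert t.statistic == pytest.approx(2.0, rel=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        basis = SplineBasis(10.0, 1, (0.0, 100.0))
        times = rng.uniform(0, 100, 20)
        y = rng.normal(size=20)
        groups = np.where(rng.random(20) < 0.5, "ISR", "NO_ISR")
        if len(set(groups)) < 2:
            groups[0] = "ISR"; groups[1] = "NO_ISR"
        t1 = tvi_statistic(y, times, groups, basis)
        t2 = tvi_statistic(3.7 * y, times, groups, basis)
        t3 = tvi_statistic(y + 11.0, times, groups, basis)
        assert t2.statistic == pytest.approx(t1.statistic, rel=1e-9)
        assert t3.statistic == pytest.approx(t1.statistic, rel=1e-6)

    def test_degenerate_perfect_fit_flagged_infinite(self):
        basis = SplineBasis(10.0, 0, (0.0, 20.0))
        times = [1, 20, 1, 20]
        y = [1.0, 2.0, 5.0, 9.0]  # one obs per group x segment: rss_alt = 0
        groups = ["ISR", "ISR", "NO_ISR", "NO_ISR"]
        t = tvi_statistic(y, times, groups, basis)
        assert t.degenerate and np.isinf(t.statistic)

    def test_single_group_error(self):
        basis = SplineBasis(10.0, 0, (0.0, 20.0))
        with pytest.raises(ValidationError):
            tvi_statistic([1, 2], [1, 20], ["ISR", "ISR"], basis)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_degree0_matches_segment_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 25))
        knot = 10.0
        times = rng.uniform(0, 20, size=n)
        # ensure both segments and both groups populated
        times[:2] = [1.0, 15.0]
        groups = np.where(rng.random(n) < 0.5, "ISR", "NO_ISR")
        groups[:2] = ["ISR", "NO_ISR"]
        y = rng.normal(size=n)
        basis = SplineBasis(knot, 0, (0.0, 20.0))
        t = tvi_statistic(y, times, groups, basis)
        rss_null, rss_alt, T = degree0_statistic_oracle(y, times, groups, knot)
        assert t.rss_null == pytest.approx(rss_null, rel=1e-10, abs=1e-12)
        assert t.rss_alt == pytest.approx(rss_alt, rel=1e-10, abs=1e-12)
        if rss_alt > 0:
            assert t.statistic == pytest.approx(T, rel=1e-10, abs=1e-12)

    @given(st.integers(0, 10_000), st.sampled_from([0, 1]))
    @settings(max_examples=60, deadline=None)
    def test_nesting_invariant(self, seed, degree):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        times = rng.uniform(0, 30, size=n)
        times[:2] = [2.0, 25.0]
        groups = np.where(rng.random(n) < 0.5, "ISR", "NO_ISR")
        groups[:2] = ["ISR", "NO_ISR"]
        y = rng.normal(size=n)
        basis = SplineBasis(12.0, degree, (0.0, 30.0))
        t = tvi_statistic(y, times, groups, basis)
        assert t.rss_alt <= t.rss_null
        assert t.statistic >= 0.0


class TestBootstrap:
    def _design(self, seed=0, n_subj=20):
        rng = np.random.default_rng(seed)
        times, groups, subjects = [], [], []
        for i in range(n_subj):
            g = "ISR" if i < n_subj // 2 else "NO_ISR"
            for t in [0.0, float(rng.uniform(14, 28)), float(rng.uniform(150, 210))]:
                times.append(t)
                groups.append(g)
                subjects.append(f"P{i}")
        return np.array(times), np.array(groups, dtype=object), subjects

    def test_zero_statistic_gives_p_one(self):
        # both groups carry identical data at identical (shared) times
        n_subj = 10
        times, groups, subjects = [], [], []
        for i in range(n_subj):
            g = "ISR" if i < n_subj // 2 else "NO_ISR"
            for t in (0.0, 20.0, 180.0):
                times.append(t); groups.append(g); subjects.append(f"P{i}")
        times = np.array(times)
        groups = np.array(groups, dtype=object)
        basis = build_tvi_basis(times, knot_policy="fixed", knot=20.0)
        rng = np.random.default_rng(3)
        y = rng.normal(size=len(times))
        half = len(times) // 2
        y[half:] = y[:half]
        t = bootstrap_pvalue(y, times, groups, basis, n_bootstrap=99, seed=1,
                             subject_ids=subjects)
        assert t.statistic == pytest.approx(0.0, abs=1e-9)
        assert t.p_value == 1.0

    def test_same_seed_reproducible(self):
        times, groups, subjects = self._design(1)
        basis = build_tvi_basis(times)
        y = np.random.default_rng(4).normal(size=len(times))
        a = bootstrap_pvalue(y, times, groups, basis, 199, seed=7, subject_ids=subjects)
        b = bootstrap_pvalue(y, times, groups, basis, 199, seed=7, subject_ids=subjects)
        assert a.p_value == b.p_value

    def test_pvalue_in_unit_interval_add_one_convention(self):
        times, groups, subjects = self._design(2)
        basis = build_tvi_basis(times)
        y = np.random.default_rng(5).normal(size=len(times))
        t = bootstrap_pvalue(y, times, groups, basis, 99, seed=0, subject_ids=subjects)
        assert 1 / 100 <= t.p_value <= 1.0

    def test_iid_scheme_runs_without_subjects(self):
        times, groups, _ = self._design(3)
        basis = build_tvi_basis(times)
        y = np.random.default_rng(6).normal(size=len(times))
        t = bootstrap_pvalue(y, times, groups, basis, 99, seed=0, scheme="iid_residual")
        assert 0 < t.p_value <= 1

    def test_block_scheme_requires_subjects(self):
        times, groups, _ = self._design(4)
        basis = build_tvi_basis(times)
        with pytest.raises(ValidationError):
            bootstrap_pvalue(np.zeros(len(times)) + 1, times, groups, basis, 9, seed=0)

    def test_invalid_n_bootstrap(self):
        times, groups, subjects = self._design(5)
        basis = build_tvi_basis(times)
        with pytest.raises(ValidationError):
            bootstrap_pvalue(np.ones(len(times)), times, groups, basis, 0, seed=0,
                             subject_ids=subjects)

    def test_null_pvalues_roughly_uniform(self):
        # calibration at small scale: 200 null genes, KS test vs uniform
        from scipy import stats

        times, groups, subjects = self._design(6, n_subj=16)
        basis = build_tvi_basis(times)
        tester = TviTester(times, groups, basis, subject_ids=subjects)
        rng = np.random.default_rng(7)
        subj_index = np.array([int(s[1:]) for s in subjects])
        pvals = []
        for g in range(200):
            b = rng.normal(0, 0.3, size=16)[subj_index]
            y = 8.0 + b + rng.normal(0, 0.5, size=len(times))
            pvals.append(tester.bootstrap(y, 999, seed=rng.integers(2**32)).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
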