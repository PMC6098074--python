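"""Normality-gated tests, proportions, dip statistic and the cluster scan."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import linprog
from sklearn.decomposition import PCA

from crtuning import stats


# ----------------------------------------------------------------- oracle
def dip_lp_oracle(x):
    """Exact dip by linear programming over piecewise-linear unimodal CDFs.

    For each candidate mode, searches the closest CDF that is convex below
    and concave above the mode (jump allowed at the mode) in sup-norm.
    Independent of the production algorithm; tractable for small samples.
    """
    x = np.sort(np.asarray(x, float))
    n = x.size
    u, counts = np.unique(x, return_counts=True)
    m = u.size
    if m == 1:
        return 1.0 / (2 * n)
    c = np.cumsum(counts) / n
    clo = np.concatenate([[0.0], c[:-1]])
    best = np.inf
    for k in range(m):
        nv = m + 2
        idx = lambda j: j if j <= k else j + 1   # noqa: E731
        L, R, D = k, k + 1, m + 1
        A, b = [], []

        def le(co, rhs):
            row = np.zeros(nv)
            for i, w in co.items():
                row[i] += w
            A.append(row)
            b.append(rhs)

        for j in range(m):
            if j == k:
                continue
            i = idx(j)
            le({i: -1.0, D: -1.0}, -c[j])
            le({i: 1.0, D: -1.0}, clo[j])
        le({L: -1.0, D: -1.0}, -clo[k])
        le({L: 1.0, D: -1.0}, clo[k])
        le({R: -1.0, D: -1.0}, -c[k])
        le({R: 1.0, D: -1.0}, c[k])
        for i in range(nv - 2):
            le({i: 1.0, i + 1: -1.0}, 0.0)
        le({0: -1.0}, 0.0)
        le({m: 1.0}, 1.0)
        for j in range(1, k):       # convex branch
            dx1, dx2 = u[j] - u[j - 1], u[j + 1] - u[j]
            le({(L if j + 1 == k else j + 1): -dx1, j: dx1 + dx2,
                j - 1: -dx2}, 0.0)
        for j in range(k + 1, m - 1):  # concave branch
            dx1, dx2 = u[j] - u[j - 1], u[j + 1] - u[j]
            le({idx(j + 1): dx1, idx(j): -(dx1 + dx2),
                (R if j - 1 == k else idx(j - 1)): dx2}, 0.0)
        cvec = np.zeros(nv)
        cvec[D] = 1.0
        res = linprog(cvec, A_ub=np.array(A), b_ub=np.array(b),
                      bounds=[(None, None)] * (nv - 1) + [(0, None)],
                      method="highs")
        if res.status == 0:
            best = min(best, res.fun)
    return max(best, 1.0 / (2 * n))


class TestGroupComparisons:
    def test_identical_samples_are_not_different(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        res = stats.compare_two_groups(a, a.copy())
        assert res.p_value > 0.9

    def test_exponential_samples_route_to_mann_whitney(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(20):
            res = stats.compare_two_groups(rng.exponential(1, 40),
                                           rng.exponential(1, 40))
            hits += res.test_name == "mann_whitney"
        assert hits >= 18  # Shapiro nearly always rejects exponentials at n=40

    def test_separated_normals_use_t_test_with_power(self):
        rng = np.random.default_rng(2)
        routed, strong = 0, 0
        for _ in range(20):
            res = stats.compare_two_groups(rng.normal(0, 1, 50),
                                           rng.normal(2, 1, 50))
            routed += res.test_name == "t"
            strong += res.p_value < 1e-6
        assert routed >= 17 and strong >= 19

    def test_gate_consistency_between_name_and_normality(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            a = rng.exponential(1, 30) if rng.random() < 0.5 else rng.normal(0, 1, 30)
            b = rng.normal(0, 1, 30)
            res = stats.compare_two_groups(a, b)
            both_normal = (res.normality_p_a >= 0.05 and res.normality_p_b >= 0.05)
            assert (res.test_name == "t") == both_normal

    def test_paired_route_is_wilcoxon(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 30)
        res = stats.compare_two_groups(a, a + rng.normal(0.5, 0.2, 30), paired=True)
        assert res.test_name == "wilcoxon_signed_rank" and res.p_value < 1e-3

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            stats.compare_two_groups([1, 2], [3, 4, 5])


class TestProportions:
    def test_identical_proportions_give_p_one(self):
        assert stats.compare_proportions(10, 100, 10, 100).p_value == 1.0

    def test_maximal_separation(self):
        assert stats.compare_proportions(0, 50, 50, 50).p_value < 1e-10

    def test_matches_textbook_chi_square_formula(self):
        # 2x2 table [[30,20],[10,40]]: chi2 = N(ad-bc)^2 / row/col products
        res = stats.compare_proportions(30, 50, 10, 50)
        a, b, c, d = 30, 20, 10, 40
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.p_value == pytest.approx(float(sps.chi2.sf(expected, 1)), rel=1e-9)

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            stats.compare_proportions(5, 3, 1, 10)


class TestFriedman:
    def test_two_treatments_with_consistent_ordering(self):
        m = np.array([[1.0, 2.0]] * 5)  # treatment 2 always larger, 5 blocks
        res = stats.friedman_test(m)
        assert res.statistic == pytest.approx(5.0)
        assert res.p_value == pytest.approx(float(sps.chi2.sf(5.0, 1)), rel=1e-9)

    def test_matches_scipy_for_three_treatments(self):
        rng = np.random.default_rng(5)
        m = rng.normal(0, 1, (12, 3))
        ours = stats.friedman_test(m)
        ref = sps.friedmanchisquare(m[:, 0], m[:, 1], m[:, 2])
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestCorrelation:
    def test_identity_gives_r_one(self):
        x = np.linspace(0, 1, 20)
        r, p = stats.calcium_spike_correlation(x, x)
        assert r == pytest.approx(1.0) and p < 1e-20

    def test_constant_vector_is_flagged(self):
        r, p = stats.calcium_spike_correlation(np.ones(10), np.linspace(0, 1, 10))
        assert np.isnan(r) and np.isnan(p)

    def test_permutation_p_detects_strong_correlation(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 40)
        y = x + rng.normal(0, 0.3, 40)
        r, p = stats.permutation_correlation(x, y, n_perm=2000, seed=1)
        assert r > 0.9 and p < 2e-3


class TestDipStatistic:
    def test_two_distinct_points_reach_the_lower_bound(self):
        assert stats.dip_statistic([0.0, 1.0]) == pytest.approx(0.25, abs=1e-9)

    def test_equally_spaced_grid_is_maximally_unimodal(self):
        assert stats.dip_statistic(np.linspace(0, 1, 100)) == \
            pytest.approx(0.005, abs=1e-9)

    def test_two_point_masses_approach_the_upper_bound(self):
        x = np.concatenate([np.zeros(50), np.full(50, 10.0)])
        d = stats.dip_statistic(x)
        assert d > 0.2 and d <= 0.25

    def test_matches_lp_oracle_on_small_samples(self):
        rng = np.random.default_rng(7)
        for trial in range(25):
            n = int(rng.integers(2, 13))
            kind = trial % 4
            if kind == 0:
                x = rng.uniform(size=n)
            elif kind == 1:
                x = np.exp(rng.normal(size=n) * 2)
            elif kind == 2:
                x = np.concatenate([rng.normal(0, 1, n), rng.normal(8, 1, n)])
            else:
                x = np.round(rng.uniform(0, 3, n))
            assert stats.dip_statistic(x) == pytest.approx(dip_lp_oracle(x),
                                                           abs=1e-7)

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.normal(0, 1, 60)
            d = stats.dip_statistic(x)
            assert stats.dip_statistic(3.7 * x - 11.0) == pytest.approx(d, abs=1e-9)
            assert stats.dip_statistic(-x) == pytest.approx(d, abs=1e-9)

    def test_bounds_hold_on_random_samples(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(2, 200))
            d = stats.dip_statistic(rng.standard_cauchy(n))
            assert 1.0 / (2 * n) - 1e-12 <= d <= 0.25 + 1e-12

    def test_all_equal_returns_convention_minimum(self):
        assert stats.dip_statistic(np.full(10, 3.0)) == pytest.approx(0.05)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            stats.dip_statistic([1.0])
        with pytest.raises(ValueError):
            stats.dip_statistic([1.0, np.nan])


class TestDipPvalue:
    def test_minimal_dip_has_p_near_one(self):
        null = stats.dip_null_table(50, n_boot=1000, seed=0)
        p = stats.dip_pvalue(1 / 100.0, 50, null_table=null)
        assert p > 0.95

    def test_uniform_null_calibration(self):
        """p-values of uniform samples are approximately uniform."""
        n, reps = 100, 500
        null = stats.dip_null_table(n, n_boot=2000, seed=1)
        rng = np.random.default_rng(10)
        ps = np.sort([stats.dip_pvalue(stats.dip_statistic(rng.random(n)), n,
                                       null_table=null) for _ in range(reps)])
        ks = np.max(np.abs(ps - (np.arange(1, reps + 1)) / reps))
        assert ks < 0.08

    def test_power_against_two_well_separated_clusters(self):
        n = 200
        null = stats.dip_null_table(n, n_boot=2000, seed=2)
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(100):
            x = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(6, 1, n // 2)])
            hits += stats.dip_pvalue(stats.dip_statistic(x), n, null_table=null) < 0.01
        assert hits >= 95

    def test_reproducible_given_seed(self):
        a = stats.dip_null_table(30, 1000, seed=5)
        stats._NULL_CACHE.clear()
        b = stats.dip_null_table(30, 1000, seed=5)
        assert np.array_equal(a, b)


class TestClusterScan:
    @staticmethod
    def _table(n=60, seed=0, separated=False):
        rng = np.random.default_rng(seed)
        cols = {f: rng.normal(0, 1, n) for f in stats.CLUSTER_FEATURES}
        cols["depth_um"] = rng.uniform(120, 350, n)
        if separated:
            # joint two-feature separation: the shared cluster axis survives
            # z-scoring and dominates the pair's first principal component
            shift = np.repeat([0.0, 6.0], [n // 2, n - n // 2])
            cols["osi"] = rng.normal(0, 1, n) + shift
            cols["dsi"] = rng.normal(0, 1, n) + shift
        return pd.DataFrame(cols)

    def test_seven_features_give_56_subsets(self):
        res = stats.cluster_scan(self._table(), n_boot=1000, seed=3)
        assert len(res) == 56
        assert all(r.n_tests == 56 for r in res)

    def test_bonferroni_never_decreases_and_caps_at_one(self):
        res = stats.cluster_scan(self._table(seed=4), n_boot=1000, seed=4)
        for r in res:
            assert r.p_bonferroni >= r.p_raw - 1e-15
            assert r.p_bonferroni <= 1.0

    def test_separated_clusters_are_detected(self):
        res = stats.cluster_scan(self._table(n=150, seed=5, separated=True),
                                 n_boot=2000, seed=5)
        assert min(r.p_bonferroni for r in res) < 0.05

    def test_missing_rows_are_dropped_per_subset(self):
        t = self._table(n=40, seed=6)
        t.loc[:35, "c50"] = np.nan   # c50 subsets fall below the minimum n
        res = stats.cluster_scan(t, n_boot=1000, seed=6)
        tested = {r.feature_subset for r in res}
        assert all("c50" not in s for s in tested)
        assert all(r.n_tests == len(res) for r in res)

    def test_pc1_of_symmetric_pair_is_the_45_degree_projection(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 300)
        y = 0.8 * x + rng.normal(0, 0.6, 300)
        z = np.column_stack([(x - x.mean()) / x.std(), (y - y.mean()) / y.std()])
        pc1 = PCA(n_components=1).fit(z).components_[0]
        assert abs(abs(pc1[0]) - abs(pc1[1])) < 1e-10
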