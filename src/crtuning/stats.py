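"""Group statistics, the calcium-spiking validation and the cluster scan.

Two-group comparisons are gated by Shapiro-Wilk normality at the 5% level:
Student t-test when both samples are normal, Mann-Whitney U otherwise;
paired comparisons use the Wilcoxon signed-rank test.  Proportions are
compared with a plain (uncorrected) chi-square on the 2x2 table.

The cluster scan z-scores every pair and triplet of tuning metrics (depth
jittered to undo shared-session depths), projects on the first principal
component and applies Hartigan's dip test with a uniform-null Monte-Carlo
p-value, Bonferroni-corrected over the number of subsets.

The dip statistic here is exact: the minimal sup-norm distance between the
empirical CDF and any unimodal CDF (convex below the mode, concave above,
with an atom allowed at the mode).  For each candidate mode the cost is the
larger of two one-sided convex/concave band-fitting costs plus a coupling
constraint joining the two branches; the minimum over modes is found by
bisection on the band radius.  The statistic is affine-invariant (it is not
invariant under nonlinear monotone transforms, which genuinely change how
clustered the spacings are).
"""
from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats as sps
from sklearn.decomposition import PCA

log = logging.getLogger("crtuning")

NORMALITY_ALPHA = 0.05
DEFAULT_N_BOOT = 10_000
DEPTH_JITTER_UM = 10.0
MIN_SUBSET_OBS = 8

CLUSTER_FEATURES = ("depth_um", "osi", "dsi", "si", "sf_halfmax_high",
                    "tf_halfmax_high", "c50")


# --------------------------------------------------------------------------
# group comparisons
# --------------------------------------------------------------------------
@dataclasses.dataclass
class GroupTestResult:
    test_name: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    normality_p_a: float = np.nan
    normality_p_b: float = np.nan

    def as_dict(self):
        return dataclasses.asdict(self)


def _shapiro_p(x):
    x = np.asarray(x, float)
    if np.ptp(x) == 0:
        log.info("zero-variance sample: routed to the nonparametric path")
        return 0.0
    return float(sps.shapiro(x).pvalue)


def compare_two_groups(a, b, paired: bool = False,
                       equal_var: bool = True) -> GroupTestResult:
    """Normality-gated two-group comparison (two-sided).

    Unpaired: Student t-test if both samples pass Shapiro-Wilk at 5%,
    Mann-Whitney U otherwise.  Paired: Wilcoxon signed-rank (the paired
    route is nonparametric throughout); normality p-values are still
    reported for reference.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need n >= 3 per group for the normality gate")
    if paired and len(a) != len(b):
        raise ValueError("paired comparison needs equal-length samples")
    pa, pb = _shapiro_p(a), _shapiro_p(b)
    if paired:
        d = a - b
        if np.all(d == 0):
            log.info("paired comparison with all-zero differences; p=1")
            return GroupTestResult("wilcoxon_signed_rank", 0.0, 1.0,
                                   len(a), len(b), pa, pb)
        st = sps.wilcoxon(a, b)
        return GroupTestResult("wilcoxon_signed_rank", float(st.statistic),
                               float(st.pvalue), len(a), len(b), pa, pb)
    if pa >= NORMALITY_ALPHA and pb >= NORMALITY_ALPHA:
        st = sps.ttest_ind(a, b, equal_var=equal_var)
        return GroupTestResult("t", float(st.statistic), float(st.pvalue),
                               len(a), len(b), pa, pb)
    st = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupTestResult("mann_whitney", float(st.statistic), float(st.pvalue),
                           len(a), len(b), pa, pb)


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> GroupTestResult:
    """Chi-square (no continuity correction) on the 2x2 count table."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 == 0 or n2 == 0:
        raise ValueError("need 0 <= k <= n and n > 0")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a margin of the 2x2 table is zero")
    if k1 == 0 and k2 == 0 or k1 == n1 and k2 == n2:
        return GroupTestResult("chi2", 0.0, 1.0, n1, n2)
    res = sps.chi2_contingency(table, correction=False)
    return GroupTestResult("chi2", float(res.statistic), float(res.pvalue), n1, n2)


def compare_multiple_groups(groups) -> GroupTestResult:
    """Kruskal-Wallis across >= 3 independent groups."""
    st = sps.kruskal(*groups)
    return GroupTestResult("kruskal_wallis", float(st.statistic), float(st.pvalue),
                           len(groups[0]), len(groups[-1]))


def friedman_test(block_matrix) -> GroupTestResult:
    """Friedman chi-square with tie correction; blocks in rows, treatments
    in columns.  Works for two treatments (where scipy requires three)."""
    m = np.asarray(block_matrix, float)
    nb, k = m.shape
    if nb < 2 or k < 2:
        raise ValueError("need >= 2 blocks and >= 2 treatments")
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    rsum = ranks.sum(axis=0)
    stat = 12.0 / (nb * k * (k + 1)) * np.sum(rsum ** 2) - 3.0 * nb * (k + 1)
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts ** 3 - counts)
    corr = 1.0 - ties / (nb * (k ** 3 - k))
    if corr <= 0:
        return GroupTestResult("friedman", 0.0, 1.0, nb, k)
    stat /= corr
    p = float(sps.chi2.sf(stat, k - 1))
    return GroupTestResult("friedman", float(stat), p, nb, k)


# --------------------------------------------------------------------------
# calcium-vs-spiking validation
# --------------------------------------------------------------------------
def calcium_spike_correlation(normalized_calcium, normalized_spikes):
    """Pearson r and regression-slope p between paired response vectors."""
    x = np.asarray(normalized_calcium, float)
    y = np.asarray(normalized_spikes, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of >= 3 measurements")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.info("degenerate correlation input (zero variance)")
        return np.nan, np.nan
    r = float(sps.pearsonr(x, y).statistic)
    slope_p = float(sps.linregress(x, y).pvalue)
    return r, slope_p


def permutation_correlation(x, y, n_perm=10_000, seed=0):
    """Pearson r with a two-sided permutation p-value (seeded)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    r = float(sps.pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    count = 0
    for _ in range(n_perm):
        rp = float(xc @ rng.permutation(yc)) / denom
        if abs(rp) >= abs(r) - 1e-15:
            count += 1
    return r, (count + 1) / (n_perm + 1)


# --------------------------------------------------------------------------
# Hartigan's dip statistic (exact)
# --------------------------------------------------------------------------
@njit(cache=True)
def _side_costs(u, C, Clo):
    """One-sided convex cost (in counts) for the mode at each point.

    Incremental lower hull of the ECDF's lower corners; the cost at k is the
    largest gap of an upper corner above the hull chords among points before
    the mode (the mode point itself only needs its lower corner)."""
    m = u.size
    A = np.zeros(m)
    hull = np.empty(m, np.int64)
    hmax = np.empty(m)
    hull[0] = 0
    hmax[0] = 0.0
    h = 1
    for k in range(1, m):
        while h >= 2:
            i2 = hull[h - 1]
            i1 = hull[h - 2]
            if (Clo[k] - Clo[i2]) * (u[i2] - u[i1]) >= (Clo[i2] - Clo[i1]) * (u[k] - u[i2]):
                break
            h -= 1
        a = hull[h - 1]
        sl = (Clo[k] - Clo[a]) / (u[k] - u[a])
        prev = hmax[h - 1]
        best = 0.0
        bestfull = 0.0
        for j in range(a, k + 1):
            d = C[j] - (Clo[a] + sl * (u[j] - u[a]))
            if j < k and d > best:
                best = d
            if d > bestfull:
                bestfull = d
        A[k] = prev if prev > best else best
        hull[h] = k
        hmax[h] = prev if prev > bestfull else bestfull
        h += 1
    return A


@njit(cache=True)
def _lmin_all(u, C, Clo, dc, out):
    """Minimal convex-branch value at each point for band radius dc (counts)."""
    m = u.size
    S = np.zeros(m)
    for j in range(1, m):
        low = C[j] - dc
        s = 0.0
        for i in range(j):
            v = (low - (Clo[i] + dc)) / (u[j] - u[i])
            if v > s:
                s = v
        S[j] = s
    for k in range(m):
        best = Clo[k] - dc
        for j in range(k):
            v = (C[j] - dc) + S[j] * (u[k] - u[j])
            if v > best:
                best = v
        out[k] = best


@njit(cache=True)
def _dip_counts(u, C, Clo, n):
    m = u.size
    A = _side_costs(u, C, Clo)
    ur = -u[::-1].copy()
    Cr = n - Clo[::-1]
    Clor = n - C[::-1]
    B = _side_costs(ur, Cr, Clor)[::-1].copy()
    sides = np.empty(m)
    for k in range(m):
        sides[k] = A[k] if A[k] > B[k] else B[k]
    lo = sides.min() * 0.5
    hi = 0.25 * n + 1.0
    if hi < lo:
        hi = lo
    Lmin = np.empty(m)
    Rrev = np.empty(m)
    tol = 1e-9

    def feasible(dc):
        _lmin_all(u, C, Clo, dc, Lmin)
        _lmin_all(ur, Cr, Clor, dc, Rrev)
        for k in range(m):
            if sides[k] <= 2 * dc + tol and Lmin[k] <= (n - Rrev[m - 1 - k]) + tol:
                return True
        return False

    if feasible(lo):
        return lo
    for _ in range(64):
        if hi - lo <= 1e-11 * (1.0 + n):
            break
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            hi = mid
        else:
            lo = mid
    return hi


def dip_statistic(x) -> float:
    """Exact Hartigan dip of a sample; lies in [1/(2n), 1/4].

    All-equal samples return the minimum 1/(2n) by convention.
    """
    x = np.asarray(x, float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("dip needs at least 2 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip input must be finite")
    u, counts = np.unique(x, return_counts=True)
    if u.size == 1:
        log.info("dip of an all-equal sample: 1/(2n) by convention")
        return 1.0 / (2 * n)
    C = np.cumsum(counts).astype(np.float64)
    Clo = C - counts
    dc = _dip_counts(u.astype(np.float64), C, Clo, float(n))
    return float(min(max(dc / n, 1.0 / (2 * n)), 0.25))


_NULL_CACHE: dict = {}


def dip_null_table(n: int, n_boot: int = DEFAULT_N_BOOT, seed: int = 0) -> np.ndarray:
    """Monte-Carlo null dips from uniform samples of size n (cached)."""
    key = (int(n), int(n_boot), int(seed))
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(np.random.SeedSequence([seed, n, n_boot]))
        _NULL_CACHE[key] = np.array(
            [dip_statistic(rng.random(n)) for _ in range(n_boot)])
    return _NULL_CACHE[key]


def dip_pvalue(d: float, n: int, n_boot: int = DEFAULT_N_BOOT, seed: int = 0,
               null_table: np.ndarray | None = None) -> float:
    """p = smoothed fraction of uniform-null dips >= d."""
    if n_boot < 1000 and null_table is None:
        raise ValueError("n_boot must be >= 1000")
    null = dip_null_table(n, n_boot, seed) if null_table is None else null_table
    return float((np.sum(null >= d - 1e-15) + 1) / (null.size + 1))


# --------------------------------------------------------------------------
# PCA + dip cluster scan
# --------------------------------------------------------------------------
@dataclasses.dataclass
class DipScanResult:
    feature_subset: tuple
    n_obs: int
    dip: float
    p_raw: float
    p_bonferroni: float
    n_tests: int

    def as_dict(self):
        d = dataclasses.asdict(self)
        d["feature_subset"] = list(self.feature_subset)
        return d


def cluster_scan(feature_table: pd.DataFrame, feature_names=CLUSTER_FEATURES,
                 n_boot: int = DEFAULT_N_BOOT, seed: int = 0,
                 depth_feature: str = "depth_um",
                 jitter_um: float = DEPTH_JITTER_UM,
                 min_obs: int = MIN_SUBSET_OBS) -> list[DipScanResult]:
    """Dip-test every pair and triplet of metrics on PC1 scores.

    Features are z-scored per subset after dropping rows with missing
    values; the depth column receives seeded uniform +-jitter once per scan
    (cells recorded together share a depth, which would fake clustering).
    Bonferroni correction uses the number of subsets scanned.
    """
    feature_names = [f for f in feature_names if f in feature_table.columns]
    if len(feature_names) < 2:
        raise ValueError("need at least 2 available features")
    rng = np.random.default_rng(seed)
    table = feature_table.loc[:, feature_names].copy()
    if depth_feature in table:
        table[depth_feature] = table[depth_feature] + rng.uniform(
            -jitter_um, jitter_um, size=len(table))
    subsets = [s for r in (2, 3) for s in itertools.combinations(feature_names, r)]
    results = []
    skipped = 0
    for subset in subsets:
        sub = table.loc[:, list(subset)].dropna()
        if len(sub) < min_obs:
            log.info("cluster_scan: subset %s skipped (%d complete rows)",
                     subset, len(sub))
            skipped += 1
            continue
        z = (sub - sub.mean()) / sub.std(ddof=0)
        if not np.all(np.isfinite(z.to_numpy())):
            log.info("cluster_scan: subset %s skipped (zero-variance feature)", subset)
            skipped += 1
            continue
        pc1 = PCA(n_components=1).fit_transform(z.to_numpy())[:, 0]
        d = dip_statistic(pc1)
        # the uniform null depends only on n: a fixed seed keeps the table
        # reusable across scans (and across subsets of equal size)
        p = dip_pvalue(d, len(pc1), n_boot=n_boot, seed=0)
        results.append(DipScanResult(subset, len(pc1), d, p, np.nan, 0))
    n_tests = len(results)
    for r in results:
        r.n_tests = n_tests
        r.p_bonferroni = min(1.0, r.p_raw * n_tests)
    if skipped:
        log.info("cluster_scan: %d of %d subsets skipped", skipped, len(subsets))
    return sorted(results, key=lambda r: r.p_bonferroni)
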