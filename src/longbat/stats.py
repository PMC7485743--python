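"""Statistical primitives shared by all pipeline stages.

Every hypothesis test the pipeline reports is computed by code in this
module: exact enumeration (via dynamic programming equivalent to full
enumeration) where the null distribution is small enough, asymptotic
approximations with tie corrections otherwise.  The ``TestResult.exact``
flag records which route produced each p-value.

Conventions
-----------
* ``alternative`` is one of ``"greater"``, ``"less"``, ``"two_sided"``.
* Exact switchover thresholds are fixed constants (signed-rank: n <= 25
  after zero removal; rank-sum: n_x + n_y <= 20 and no ties) so results
  are reproducible across platforms.
* The highest density interval (HDI) is defined directly on the empirical
  sample — the shortest contiguous window over the sorted values holding
  at least the requested mass — with ties broken toward the smallest
  lower bound.  No density smoothing is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from math import comb, erfc, lgamma

import numpy as np

ALTERNATIVES = ("greater", "less", "two_sided")

# exact-vs-approximate switchovers (kept as module constants for reproducibility)
SIGNED_RANK_EXACT_LIMIT = 25
RANK_SUM_EXACT_LIMIT = 20


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test."""

    statistic: float
    p_value: float
    alternative: str
    method: str
    exact: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0,1]: {self.p_value}")
        if self.alternative not in ALTERNATIVES:
            raise ValueError(f"unknown alternative: {self.alternative}")


@dataclass(frozen=True)
class Interval:
    """A closed interval together with the probability mass it holds."""

    lower: float
    upper: float
    mass: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower > upper")
        if not (0.0 < self.mass <= 1.0):
            raise ValueError("mass must be in (0, 1]")

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


def _check_alternative(alternative: str) -> None:
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")


def midrank(values) -> np.ndarray:
    """Mid-ranks (average ranks for ties), 1-based."""
    a = np.asarray(values, dtype=float)
    order = np.argsort(a, kind="mergesort")
    ranks = np.empty(a.size, dtype=float)
    sa = a[order]
    i = 0
    while i < a.size:
        j = i
        while j + 1 < a.size and sa[j + 1] == sa[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _norm_sf(z: float) -> float:
    return 0.5 * erfc(z / math.sqrt(2.0))


def _tie_term(values: np.ndarray) -> float:
    """sum(t^3 - t) over tied groups."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


@lru_cache(maxsize=4096)
def _signed_rank_counts(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Counts of 2*W+ over all 2^n sign assignments (DP == enumeration)."""
    total = sum(doubled_ranks)
    ways = np.zeros(total + 1)
    ways[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(ways)
        shifted[r:] = ways[: ways.size - r]
        ways = ways + shifted
    return ways


def wilcoxon_signed_rank(differences, alternative: str = "greater") -> TestResult:
    """Wilcoxon signed-rank test for paired differences.

    Zero differences are dropped before ranking (Wilcoxon's original
    convention).  The statistic is W+, the sum of ranks of positive
    differences.  For n <= 25 after zero removal the null distribution of
    W+ is fully enumerated; otherwise a normal approximation with tie
    correction and 0.5 continuity correction is used.
    """
    _check_alternative(alternative)
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("degenerate paired sample: all differences are zero")
    absd = np.abs(d)
    ranks = midrank(absd)
    w_plus = float(ranks[d > 0].sum())

    if n <= SIGNED_RANK_EXACT_LIMIT:
        doubled = tuple(sorted(int(round(2.0 * r)) for r in ranks))
        counts = _signed_rank_counts(doubled)
        total = 2.0**n
        w2 = int(round(2.0 * w_plus))
        p_ge = float(counts[w2:].sum() / total)
        p_le = float(counts[: w2 + 1].sum() / total)
        exact, method = True, "wilcoxon signed-rank (exact enumeration)"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(absd) / 48.0
        if var <= 0:
            p_ge = p_le = 1.0
        else:
            sd = math.sqrt(var)
            p_ge = _norm_sf((w_plus - mu - 0.5) / sd)
            p_le = 1.0 - _norm_sf((w_plus - mu + 0.5) / sd)
        exact, method = False, "wilcoxon signed-rank (normal approximation)"

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return TestResult(w_plus, min(1.0, max(0.0, p)), alternative, method, exact)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann–Whitney)


@lru_cache(maxsize=256)
def _rank_sum_counts(nx: int, n: int) -> np.ndarray:
    """Counts of rank sums of nx distinct ranks chosen from 1..n."""
    max_s = sum(range(n - nx + 1, n + 1))
    dp = np.zeros((nx + 1, max_s + 1))
    dp[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, nx), 0, -1):
            dp[k, r:] += dp[k - 1, : max_s + 1 - r]
    return dp[nx]


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided") -> TestResult:
    """Two-sample Wilcoxon rank-sum test.

    Statistic is the rank sum of ``x`` in the pooled mid-ranked sample.
    Exact when n_x + n_y <= 20 and there are no ties; otherwise a normal
    approximation with tie correction is used.  ``alternative="less"``
    tests whether ``x`` is stochastically smaller than ``y``.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = midrank(pooled)
    w = float(ranks[:nx].sum())
    has_ties = np.unique(pooled).size < n

    if n <= RANK_SUM_EXACT_LIMIT and not has_ties:
        counts = _rank_sum_counts(nx, n)
        total = comb(n, nx)
        wi = int(round(w))
        p_le = float(counts[: wi + 1].sum() / total)
        p_ge = float(counts[wi:].sum() / total)
        exact, method = True, "wilcoxon rank-sum (exact enumeration)"
    else:
        mu = nx * (n + 1) / 2.0
        var = nx * ny / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
        if var <= 0:
            p_le = p_ge = 1.0
        else:
            sd = math.sqrt(var)
            p_ge = _norm_sf((w - mu - 0.5) / sd)
            p_le = 1.0 - _norm_sf((w - mu + 0.5) / sd)
        exact, method = False, "wilcoxon rank-sum (normal approximation)"

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return TestResult(w, min(1.0, max(0.0, p)), alternative, method, exact)


# ---------------------------------------------------------------------------
# Fisher's exact test and the hypergeometric tail


def _hypergeom_logpmf(k: int, N: int, K: int, n: int) -> float:
    return (
        lgamma(K + 1) - lgamma(k + 1) - lgamma(K - k + 1)
        + lgamma(N - K + 1) - lgamma(n - k + 1) - lgamma(N - K - n + k + 1)
        - (lgamma(N + 1) - lgamma(n + 1) - lgamma(N - n + 1))
    )


def hypergeom_sf_at_least(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    lo = max(0, n - (N - K))
    hi = min(K, n)
    if k <= lo:
        return 1.0
    if k > hi:
        return 0.0
    return min(1.0, sum(math.exp(_hypergeom_logpmf(j, N, K, n)) for j in range(k, hi + 1)))


def fisher_exact_2x2(table, alternative: str = "two_sided") -> TestResult:
    """Fisher's exact test on a 2x2 contingency table.

    One-sided p-values are exact hypergeometric tails on the top-left
    cell; the two-sided p sums all tables whose probability does not
    exceed that of the observed table (with a 1e-9 relative tolerance
    for floating-point comparisons).
    """
    _check_alternative(alternative)
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("negative cell count")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    if N == 0:
        raise ValueError("empty table")
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    logpmf = {k: _hypergeom_logpmf(k, N, r1, c1) for k in range(lo, hi + 1)}
    p_obs = logpmf[a]
    p_ge = min(1.0, sum(math.exp(logpmf[k]) for k in range(a, hi + 1)))
    p_le = min(1.0, sum(math.exp(logpmf[k]) for k in range(lo, a + 1)))
    p_two = min(
        1.0,
        sum(math.exp(lp) for lp in logpmf.values() if lp <= p_obs + 1e-9 * abs(p_obs) + 1e-12),
    )
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan
    p = {"greater": p_ge, "less": p_le, "two_sided": p_two}[alternative]
    return TestResult(odds, p, alternative, "fisher exact", True)


# ---------------------------------------------------------------------------
# Benjamini–Hochberg


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# Kolmogorov–Smirnov


def _kolmogorov_sf(t: float) -> float:
    """Asymptotic KS survival function Q(t) = 2 * sum (-1)^(k-1) exp(-2 k^2 t^2)."""
    if t <= 0:
        return 1.0
    total = 0.0
    for k in range(1, 101):
        term = 2.0 * (-1.0) ** (k - 1) * math.exp(-2.0 * k * k * t * t)
        total += term
        if abs(term) < 1e-16:
            break
    return min(1.0, max(0.0, total))


def ks_2samp(x, y) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test (asymptotic p-value).

    Statistic is the supremum distance between the two empirical CDFs.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / nx
    cdf_y = np.searchsorted(y, grid, side="right") / ny
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = math.sqrt(nx * ny / (nx + ny))
    p = _kolmogorov_sf(en * d)
    return TestResult(d, p, "two_sided", "two-sample KS (asymptotic)", False)


# ---------------------------------------------------------------------------
# Pearson chi-square on a 2x2 table


def chi2_2x2(table) -> TestResult:
    """Pearson chi-square test (no continuity correction, df = 1)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("negative cell count")
    a, b, c, d = t[0, 0], t[0, 1], t[1, 0], t[1, 1]
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("undefined expected counts: zero margin")
    n = r1 + r2
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = erfc(math.sqrt(stat / 2.0))  # chi2(df=1) survival function
    return TestResult(float(stat), min(1.0, p), "two_sided", "pearson chi-square (df=1)", False)


# ---------------------------------------------------------------------------
# Spearman correlation


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("undefined correlation: constant vector")
    rx, ry = midrank(x), midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


# ---------------------------------------------------------------------------
# Highest density interval


def hdi(sample, mass: float = 0.95) -> Interval:
    """Shortest contiguous window over the sorted sample holding ceil(mass*n) points.

    Ties in width are broken toward the smallest lower bound, making the
    result deterministic and directly checkable against an exhaustive
    window scan.
    """
    s = np.sort(np.asarray(sample, dtype=float))
    n = s.size
    if n == 0:
        raise ValueError("empty sample")
    if not (0.0 < mass <= 1.0):
        raise ValueError("mass must be in (0, 1]")
    k = min(n, math.ceil(mass * n))
    widths = s[k - 1 :] - s[: n - k + 1]
    i = int(np.argmin(widths))  # argmin returns the first (lowest) minimiser
    return Interval(float(s[i]), float(s[i + k - 1]), mass)
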