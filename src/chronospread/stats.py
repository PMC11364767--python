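"""Nonparametric statistics used across the pipeline.

Small-sample exactness matters here: the Mann-Whitney U test enumerates
all arrangements when the pooled sample is small, and the Hartigan dip
statistic is computed by an exact geometric construction rather than an
asymptotic approximation, so both can be checked against brute-force
oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "mann_whitney",
    "spearman",
    "chi_square",
    "dip_statistic",
    "dip_test",
    "shapiro_wilk",
]

#: pooled-size threshold below which the U test enumerates all arrangements
EXACT_U_THRESHOLD = 12


@dataclass
class StatResult:
    """Outcome of one hypothesis test.

    ``smaller`` names the side with the stochastically smaller sample when
    a directional comparison was significant (the "Less" column of the
    day/night tables); ``note`` carries degeneracy flags.
    """

    test: str
    statistic: float
    p: float
    sided: str = "two"
    n1: int | None = None
    n2: int | None = None
    smaller: str | None = None
    seed: int | None = None
    note: str | None = None
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p": self.p,
            "sided": self.sided,
            "n1": self.n1,
            "n2": self.n2,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: pairs with x > y, counting ties as 1/2."""
    gt = np.sum(x[:, None] > y[None, :])
    ties = np.sum(x[:, None] == y[None, :])
    return float(gt) + 0.5 * float(ties)


def mann_whitney(x, y, alternative: str = "two-sided",
                 exact_threshold: int = EXACT_U_THRESHOLD) -> StatResult:
    """Mann-Whitney U test of two independent samples.

    ``alternative="less"`` tests whether ``x`` is stochastically smaller
    than ``y``.  When ``len(x) + len(y) <= exact_threshold`` the p-value is
    exact, obtained by enumerating every assignment of the pooled values to
    the two groups (valid under ties); otherwise the normal approximation
    with tie correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires both samples to be nonempty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    u_obs = _u_statistic(x, y)

    if n1 + n2 <= exact_threshold:
        p = _exact_u_pvalue(x, y, u_obs, alternative)
        note = "exact"
    else:
        p = _approx_u_pvalue(x, y, u_obs, alternative)
        note = "normal-approximation"
    sided = "two" if alternative == "two-sided" else alternative
    return StatResult("mann-whitney", u_obs, p, sided, n1, n2, note=note)


def _exact_u_pvalue(x, y, u_obs, alternative) -> float:
    pooled = np.concatenate([x, y])
    n1 = len(x)
    idx = range(len(pooled))
    us = []
    for comb in combinations(idx, n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        us.append(_u_statistic(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    eps = 1e-9
    p_less = np.mean(us <= u_obs + eps)
    p_greater = np.mean(us >= u_obs - eps)
    if alternative == "less":
        return float(p_less)
    if alternative == "greater":
        return float(p_greater)
    return float(min(1.0, 2.0 * min(p_less, p_greater)))


def _approx_u_pvalue(x, y, u_obs, alternative) -> float:
    n1, n2 = len(x), len(y)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1.0))
    sigma2 = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if sigma2 <= 0:  # all values tied
        return 1.0
    sigma = math.sqrt(sigma2)
    # continuity-corrected z in each direction
    z_less = (u_obs - mu + 0.5) / sigma
    z_greater = (u_obs - mu - 0.5) / sigma
    p_less = sps.norm.cdf(z_less)
    p_greater = sps.norm.sf(z_greater)
    if alternative == "less":
        return float(p_less)
    if alternative == "greater":
        return float(p_greater)
    return float(min(1.0, 2.0 * min(p_less, p_greater)))


# ---------------------------------------------------------------------------
# Rank correlation and contingency tests (scipy-backed)
# ---------------------------------------------------------------------------

def spearman(x, y) -> StatResult:
    """Spearman rank correlation: Pearson correlation of midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must be paired")
    if x.size < 3:
        raise ValueError("spearman requires at least 3 paired points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return StatResult("spearman", float("nan"), float("nan"),
                          n1=x.size, note="constant-input")
    rho, p = sps.spearmanr(x, y)
    return StatResult("spearman", float(rho), float(p), n1=int(x.size))


def chi_square(table) -> StatResult:
    """Pearson chi-square test of independence on an r x c count table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need a contingency table of at least 2x2")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero-margin row or column in contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    res = StatResult("chi-square", float(chi2), float(p), n1=int(table.sum()))
    res.extra["dof"] = int(dof)
    return res


def shapiro_wilk(x) -> StatResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("shapiro_wilk supports 3 <= n <= 5000")
    w, p = sps.shapiro(x)
    return StatResult("shapiro-wilk", float(w), float(p), n1=int(x.size))


# ---------------------------------------------------------------------------
# Hartigan dip
# ---------------------------------------------------------------------------
#
# The dip of an empirical cdf F is min over unimodal cdfs G of sup|F - G|,
# where G is convex up to its mode and concave after (a jump at the mode is
# allowed).  Write the sample as distinct knots v_1 < ... < v_m with
# cumulative proportions c_j (and c_j^- just below the jump).  At level d
# the band constrains G(v_k) to [c_k - d, c_k^- + d], and constraints are
# binding at knots only, so G may be taken piecewise linear.  Splitting G
# at a junction knot r (the mode; the cdf may jump there from a left limit
# v1 to a value v2 >= v1) decomposes feasibility at level d into
#
#   (i)  a convex piece on knots < r whose band violation a_r is measured
#        against the greatest convex minorant of the upper band,
#   (ii) a concave piece on knots > r with violation b_r against the least
#        concave majorant of the lower band, and
#   (iii) a coupling threshold D3_r: every linear-certificate floor of v1
#        (band floor, monotonicity, and convex extrapolations of a lower
#        bound at k through an upper bound at j < k) must stay below every
#        cap of v2 (band cap, monotonicity, concave extrapolations), each
#        certificate being a line A - a*d or B + b*d in d.
#
# dip = min_r max(a_r/2, b_r/2, D3_r).  The construction is validated
# exactly against a linear-programming envelope oracle in the test suite.


def _prefix_gcm_dev(v: np.ndarray, upper: np.ndarray, lower: np.ndarray,
                    r: int) -> float:
    """max_{k<r} lower_k - GCM(v, upper on knots 0..r-1)(v_k); 0 if r == 1."""
    if r <= 1:
        return 0.0
    hull = [0]
    for j in range(1, r):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # keep i2 only if it lies on or below chord i1 -> j
            if (upper[i2] - upper[i1]) * (v[j] - v[i1]) <= \
               (upper[j] - upper[i1]) * (v[i2] - v[i1]):
                break
            hull.pop()
        hull.append(j)
    fit = np.interp(v[: r - 1], v[hull], upper[hull])
    return float(np.max(lower[: r - 1] - fit))


def _pareto_lines(A: np.ndarray, a: np.ndarray, keep_max: bool):
    """Drop lines that are pointwise dominated on d >= 0.

    For the max-envelope, (A, a) is dominated when some other line has
    A' >= A and slope coefficient a' <= a; mirrored for the min side.
    """
    if A.size <= 2:
        return A, a
    if keep_max:
        order = np.lexsort((-A, a))
        A, a = A[order], a[order]
        run = np.maximum.accumulate(A)
        keep = np.concatenate([[True], A[1:] > run[:-1]])
    else:
        order = np.lexsort((A, a))  # sort by a asc, A asc
        A, a = A[order], a[order]
        run = np.minimum.accumulate(A)
        keep = np.concatenate([[True], A[1:] < run[:-1]])
    return A[keep], a[keep]


def _pair_lines_left(v, U0, L0, r):
    """Certificate floor lines (A, a) with v1 >= A - a*d, junction knot r
    (1-based): convex extrapolation through (v_j, U0_j+d), (v_k, L0_k-d)."""
    parts_A = [np.array([U0[r - 1]])]
    parts_a = [np.array([1.0])]
    if r >= 2:
        parts_A.append(np.array([L0[r - 2]]))
        parts_a.append(np.array([1.0]))
    if r >= 3:
        kk, jj = np.tril_indices(r - 1, k=-1)
        gam = (v[r - 1] - v[kk]) / (v[kk] - v[jj])
        parts_A.append(L0[kk] + (L0[kk] - U0[jj]) * gam)
        parts_a.append(1.0 + 2.0 * gam)
    return _pareto_lines(np.concatenate(parts_A), np.concatenate(parts_a),
                         keep_max=True)


def _pair_lines_right(v, U0, L0, r, m):
    """Certificate cap lines (B, b) with v2 <= B + b*d."""
    parts_B = [np.array([L0[r - 1]])]
    parts_b = [np.array([1.0])]
    if r <= m - 1:
        parts_B.append(np.array([U0[r]]))
        parts_b.append(np.array([1.0]))
    if r <= m - 2:
        # pairs r <= k < j <= m-1 (0-based: k in [r, m-2], j in (k, m-1])
        jj0, kk0 = np.tril_indices(m - r, k=-1)
        kk = kk0 + r
        jj = jj0 + r
        gam = (v[kk] - v[r - 1]) / (v[jj] - v[kk])
        parts_B.append(U0[kk] + (U0[kk] - L0[jj]) * gam)
        parts_b.append(1.0 + 2.0 * gam)
    return _pareto_lines(np.concatenate(parts_B), np.concatenate(parts_b),
                         keep_max=False)


def _cross_threshold(A, a, B, b) -> float:
    """Smallest d >= 0 with A_i - a_i d <= B_j + b_j d for all pairs."""
    diff = A[:, None] - B[None, :]
    denom = a[:, None] + b[None, :]
    with np.errstate(invalid="ignore"):
        vals = diff / denom
    vals = vals[diff > 0]
    return float(vals.max()) if vals.size else 0.0


def _all_prefix_devs(v, upper, lower, m) -> np.ndarray:
    """a_r for r = 1..m via an incrementally maintained prefix hull."""
    out = np.zeros(m)
    hull = [0]
    for r in range(2, m + 1):
        j = r - 1
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            if (upper[i2] - upper[i1]) * (v[j] - v[i1]) <= \
               (upper[j] - upper[i1]) * (v[i2] - v[i1]):
                break
            hull.pop()
        hull.append(j)
        fit = np.interp(v[: r - 1], v[hull], upper[hull])
        out[r - 1] = np.max(lower[: r - 1] - fit)
    return out


def dip_statistic(x) -> float:
    """Hartigan's dip statistic of a sample (sup-distance to unimodality)."""
    x = np.asarray(x, dtype=float)
    if x.size < 1 or not np.all(np.isfinite(x)):
        raise ValueError("dip requires a nonempty finite sample")
    v, counts = np.unique(x, return_counts=True)
    m = v.size
    if m == 1:
        return 0.0
    n = x.size
    L0 = np.cumsum(counts) / n                   # c_k   = F(v_k)
    U0 = (np.cumsum(counts) - counts) / n        # c_k^- = F(v_k^-)
    # mirrored arrays for the concave side
    vm = -v[::-1]
    U0m = (1.0 - L0)[::-1]
    L0m = (1.0 - U0)[::-1]
    a_all = _all_prefix_devs(v, U0, L0, m)
    b_all = _all_prefix_devs(vm, U0m, L0m, m)[::-1]
    lower_bound = np.maximum(a_all, b_all) / 2.0
    # the coupling threshold D3 only raises a junction's value, so scan
    # junctions by their cheap lower bound and stop once no later
    # candidate can beat the best completed one
    best = np.inf
    for idx in np.argsort(lower_bound, kind="stable"):
        r = int(idx) + 1
        lo = lower_bound[idx]
        if lo >= best:
            break
        Af, af = _pair_lines_left(v, U0, L0, r)
        Bc, bc = _pair_lines_right(v, U0, L0, r, m)
        d3 = max(
            _cross_threshold(Af, af, Bc, bc),
            # v1 floors vs its own band cap U0_r + d
            _cross_threshold(Af, af, np.array([U0[r - 1]]), np.array([1.0])),
            # v2 band floor L0_r - d vs v2 caps
            _cross_threshold(np.array([L0[r - 1]]), np.array([1.0]), Bc, bc),
        )
        best = min(best, max(lo, d3))
    return float(best)


_NULL_CACHE: dict = {}


def dip_test(x, n_boot: int = 2000, seed: int | None = None) -> StatResult:
    """Dip test of unimodality, calibrated by Monte Carlo against the
    uniform null (the least-favourable unimodal distribution).

    The null dip distribution depends only on the sample size, so it is
    cached per ``(n, n_boot, seed)``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("dip_test requires n >= 4")
    d = dip_statistic(x)
    key = (x.size, n_boot, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        _NULL_CACHE[key] = np.array(
            [dip_statistic(rng.uniform(size=x.size)) for _ in range(n_boot)]
        )
    null = _NULL_CACHE[key]
    p = float((1 + np.sum(null >= d - 1e-15)) / (1 + null.size))
    res = StatResult("dip", d, p, sided="greater", n1=int(x.size), seed=seed)
    res.extra["n_boot"] = n_boot
    return res


def dip_test_curve(bin_hours, weights, n_draws: int = 10_000,
                   n_boot: int = 2000, seed: int | None = None) -> StatResult:
    """Dip test of a binned diurnal curve.

    The curve is expanded into a pseudo-sample of ``n_draws`` bin values
    weighted by mass; the null distribution is calibrated with pseudo-
    samples of the same size drawn from a uniform curve on the same grid,
    so observed and null dips share the discrete support.
    """
    bin_hours = np.asarray(bin_hours, dtype=float)
    sample = curve_to_sample(bin_hours, weights, n_draws, seed, jitter=False)
    d = dip_statistic(sample)
    key = ("grid", bin_hours.size, n_draws, n_boot, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        _NULL_CACHE[key] = np.array([
            dip_statistic(rng.choice(bin_hours, size=n_draws))
            for _ in range(n_boot)
        ])
    null = _NULL_CACHE[key]
    p = float((1 + np.sum(null >= d - 1e-15)) / (1 + null.size))
    res = StatResult("dip", d, p, sided="greater", n1=int(n_draws), seed=seed)
    res.extra["n_boot"] = n_boot
    return res


def curve_to_sample(bin_hours, weights, n_draws: int = 10_000,
                    seed: int | None = None, jitter: bool = True) -> np.ndarray:
    """Expand a binned diurnal curve into a pseudo-sample for the dip test.

    Bin start hours are weighted by their (nonnegative) mass; draws are
    jittered uniformly within each 15-minute bin so the pseudo-sample is
    continuous, as the dip's uniform calibration assumes.
    """
    bin_hours = np.asarray(bin_hours, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    p = weights / weights.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(bin_hours.size, size=n_draws, p=p)
    out = bin_hours[idx]
    if jitter:
        out = out + rng.uniform(0.0, 0.25, size=n_draws)
    return out
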