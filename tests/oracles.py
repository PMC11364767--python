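"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a different route than the
implementation: exhaustive enumeration, direct definitions, or a
linear-programming formulation.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.optimize import linprog


# ---------------------------------------------------------------------------
# Dip: LP over unimodal cdf envelopes
# ---------------------------------------------------------------------------

def dip_lp(x) -> float:
    """Dip via linear programming: for each junction knot r minimise d
    subject to a piecewise-linear cdf that is convex on knots <= r (with
    a free left limit at r, allowing a jump at the mode), concave on
    knots >= r, nondecreasing, and within the ecdf band."""
    x = np.sort(np.asarray(x, float))
    v, counts = np.unique(x, return_counts=True)
    m = v.size
    if m == 1:
        return 0.0
    n = x.size
    cum = np.cumsum(counts) / n
    cumprev = (np.cumsum(counts) - counts) / n
    best = np.inf
    for r in range(1, m + 1):
        nv = m + 2  # g_1..g_m, v1 (left limit at r), d
        c = np.zeros(nv)
        c[-1] = 1.0
        V1, D = m, m + 1
        A, b = [], []

        def row():
            return np.zeros(nv)

        for k in range(m):
            kk = k + 1
            if kk == r:
                r1 = row(); r1[V1] = -1; r1[D] = -1
                A.append(r1); b.append(-cumprev[k])
                r2 = row(); r2[V1] = 1; r2[D] = -1
                A.append(r2); b.append(cumprev[k])
                r3 = row(); r3[k] = -1; r3[D] = -1
                A.append(r3); b.append(-cum[k])
                r4 = row(); r4[k] = 1; r4[D] = -1
                A.append(r4); b.append(cum[k])
            else:
                r1 = row(); r1[k] = -1; r1[D] = -1
                A.append(r1); b.append(-cum[k])
                r2 = row(); r2[k] = 1; r2[D] = -1
                A.append(r2); b.append(cumprev[k])
        chain = list(range(r - 1)) + [V1] + list(range(r - 1, m))
        for a_i, b_i in zip(chain[:-1], chain[1:]):
            r1 = row(); r1[a_i] = 1; r1[b_i] = -1
            A.append(r1); b.append(0.0)
        pts = [(v[k], k) for k in range(r - 1)] + [(v[r - 1], V1)]
        for (x0, i0), (x1, i1), (x2, i2) in zip(pts, pts[1:], pts[2:]):
            r1 = row()
            r1[i0] += (x2 - x1); r1[i1] += -(x2 - x0); r1[i2] += (x1 - x0)
            A.append(-r1); b.append(0.0)   # convex on the left piece
        pts = [(v[k], k) for k in range(r - 1, m)]
        for (x0, i0), (x1, i1), (x2, i2) in zip(pts, pts[1:], pts[2:]):
            r1 = row()
            r1[i0] += (x2 - x1); r1[i1] += -(x2 - x0); r1[i2] += (x1 - x0)
            A.append(r1); b.append(0.0)    # concave on the right piece
        bounds = [(None, None)] * (m + 1) + [(0, None)]
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds,
                      method="highs")
        if res.success:
            best = min(best, res.fun)
    return float(best)


# ---------------------------------------------------------------------------
# Curve distances: exhaustive monotone couplings
# ---------------------------------------------------------------------------

def _couplings(n: int, m: int):
    """All monotone couplings of index sequences 0..n-1 and 0..m-1."""
    def rec(i, j, path):
        if i == n - 1 and j == m - 1:
            yield path
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                yield from rec(ni, nj, path + [(ni, nj)])
    yield from rec(0, 0, [(0, 0)])


def frechet_bruteforce(p, q) -> float:
    p, q = np.asarray(p, float), np.asarray(q, float)
    best = math.inf
    for path in _couplings(len(p), len(q)):
        cost = max(np.linalg.norm(p[i] - q[j]) for i, j in path)
        best = min(best, cost)
    return best


def dtw_bruteforce(p, q) -> float:
    p, q = np.asarray(p, float), np.asarray(q, float)
    best = math.inf
    for path in _couplings(len(p), len(q)):
        cost = sum(np.linalg.norm(p[i] - q[j]) for i, j in path)
        best = min(best, cost)
    return best


# ---------------------------------------------------------------------------
# Mann-Whitney: full arrangement enumeration
# ---------------------------------------------------------------------------

def mann_whitney_exact_oracle(x, y, alternative) -> float:
    """One/two-sided exact p by enumerating every split of the pooled
    values, with U computed by an explicit double loop."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_of(a, b):
        u = 0.0
        for xi in a:
            for yj in b:
                if xi > yj:
                    u += 1.0
                elif xi == yj:
                    u += 0.5
        return u

    u_obs = u_of(x, y)
    us = []
    for comb in combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in comb]
        b = [pooled[i] for i in range(len(pooled)) if i not in comb]
        us.append(u_of(a, b))
    us = np.asarray(us)
    p_less = np.mean(us <= u_obs + 1e-9)
    p_greater = np.mean(us >= u_obs - 1e-9)
    if alternative == "less":
        return float(p_less)
    if alternative == "greater":
        return float(p_greater)
    return float(min(1.0, 2 * min(p_less, p_greater)))


# ---------------------------------------------------------------------------
# Heightened onset: literal 96-candidate scan
# ---------------------------------------------------------------------------

def onset_bruteforce(values, n_hours) -> float:
    values = np.asarray(values, float)
    n_bins = values.size
    length = int(round(n_hours * n_bins / 24.0))
    best_sum, best_onset = -math.inf, None
    for start in range(n_bins):
        s = sum(values[(start + i) % n_bins] for i in range(length))
        if s > best_sum + 1e-12:
            best_sum, best_onset = s, start
    return best_onset * 24.0 / n_bins


# ---------------------------------------------------------------------------
# Sunrise/sunset: classic almanac algorithm (independent of the NOAA
# equations used by the implementation)
# ---------------------------------------------------------------------------

def almanac_sun_utc(lat, lon, d, zenith=90.833):
    """Sunrise and sunset (UTC datetimes) via the Almanac for Computers
    sunrise equation."""
    from datetime import datetime, timedelta, timezone

    N = d.timetuple().tm_yday
    out = []
    for rising in (True, False):
        lng_hour = lon / 15.0
        t = N + ((6 - lng_hour) / 24.0) if rising else N + ((18 - lng_hour) / 24.0)
        M = (0.9856 * t) - 3.289
        L = (M + (1.916 * math.sin(math.radians(M)))
             + (0.020 * math.sin(math.radians(2 * M))) + 282.634) % 360
        RA = math.degrees(math.atan(0.91764 * math.tan(math.radians(L)))) % 360
        Lq = (math.floor(L / 90)) * 90
        RAq = (math.floor(RA / 90)) * 90
        RA = (RA + (Lq - RAq)) / 15.0
        sin_dec = 0.39782 * math.sin(math.radians(L))
        cos_dec = math.cos(math.asin(sin_dec))
        cos_h = ((math.cos(math.radians(zenith))
                  - sin_dec * math.sin(math.radians(lat)))
                 / (cos_dec * math.cos(math.radians(lat))))
        cos_h = max(-1.0, min(1.0, cos_h))
        H = (360 - math.degrees(math.acos(cos_h))) if rising \
            else math.degrees(math.acos(cos_h))
        H /= 15.0
        T = H + RA - (0.06571 * t) - 6.622
        UT = (T - lng_hour) % 24
        out.append(datetime(d.year, d.month, d.day, tzinfo=timezone.utc)
                   + timedelta(hours=UT))
    return out
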