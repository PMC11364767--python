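"""Fourier decomposition of diurnal curves and truncated reconstruction.

A 96-sample curve over the 24-hour day is decomposed with the discrete
Fourier transform; the reconstruction keeps the DC level plus the m
non-DC harmonics of largest amplitude.  The number of harmonics m is
selected per curve with an elbow rule over a panel of curve-distance
metrics, mirroring how practitioners denoise diurnal signals while
preserving their dominant periodicities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import BIN_STARTS, DiurnalCurve, N_BINS

PERIOD_HOURS = 24.0
MAX_HARMONIC = N_BINS // 2  # Nyquist index for 96 samples

METRICS = ("pcm", "area", "frechet", "curve_length", "dtw", "mae", "mse")


@dataclass
class HarmonicModel:
    """DFT of a 96-bin curve: coefficients, amplitudes and phases.

    Amplitude of harmonic n is 2|X_n|/N for 0 < n < N/2 and |X_n|/N for
    the DC and Nyquist terms; phases are the coefficient arguments, so
    harmonic n contributes A_n cos(2 pi n t / P + phi_n) at hour t.
    """

    coefficients: np.ndarray  # rfft, length N/2 + 1
    amplitudes: np.ndarray
    phases: np.ndarray

    @property
    def dc_level(self) -> float:
        # amplitudes are magnitudes; the DC phase (0 or pi) carries the sign
        return float(self.amplitudes[0] * np.cos(self.phases[0]))


def dft(curve) -> HarmonicModel:
    """Discrete Fourier transform of a 96-bin curve."""
    values = curve.values if isinstance(curve, DiurnalCurve) else np.asarray(curve, float)
    if values.shape != (N_BINS,) or not np.all(np.isfinite(values)):
        raise ValueError(f"need {N_BINS} finite values")
    coeff = np.fft.rfft(values)
    amplitudes = np.abs(coeff) / N_BINS
    amplitudes[1:MAX_HARMONIC] *= 2.0
    phases = np.angle(coeff)
    return HarmonicModel(coeff, amplitudes, phases)


def reconstruct_top_m(model: HarmonicModel, m: int) -> DiurnalCurve:
    """Rebuild the curve from the DC level plus the m largest harmonics.

    Amplitude ties at the m-th rank are broken toward the lower frequency
    (the smoother reconstruction).  The DC term is always retained, so the
    mean of the output equals the mean of the input.
    """
    if not 1 <= m <= MAX_HARMONIC:
        raise ValueError(f"m must be in [1, {MAX_HARMONIC}]")
    kept = kept_harmonics(model, m)
    t = BIN_STARTS
    out = np.full(N_BINS, model.dc_level)
    for n in kept:
        out += harmonic_term(model, n, t)
    return DiurnalCurve(out, kind="ratio")  # may undershoot 0 slightly


def kept_harmonics(model: HarmonicModel, m: int) -> np.ndarray:
    amp = model.amplitudes[1:]  # harmonics 1..48
    order = np.argsort(-amp, kind="stable")  # stable: ties keep lower n
    return np.sort(order[:m] + 1)


def harmonic_term(model: HarmonicModel, n: int, t: np.ndarray) -> np.ndarray:
    return model.amplitudes[n] * np.cos(
        2.0 * np.pi * n * t / PERIOD_HOURS + model.phases[n])


# ---------------------------------------------------------------------------
# Curve distances
# ---------------------------------------------------------------------------
# The panel treats each curve as the planar polyline ((t_0, y_0), ...,
# (t_95, y_95)) with t in hours.  Frechet and DTW are the standard
# discrete dynamic programmes; "area" integrates |y_a - y_b| over t
# (the curves share their abscissae); "curve_length" compares total arc
# lengths; "pcm" compares the curves after normalising each to unit arc
# length, removing offset sensitivity the way partial curve mapping does.


def _as_points(y: np.ndarray, x: np.ndarray | None = None) -> np.ndarray:
    y = np.asarray(y, float)
    x = np.arange(y.size, dtype=float) * (PERIOD_HOURS / N_BINS) if x is None else x
    return np.column_stack([x, y])


def _frechet(p: np.ndarray, q: np.ndarray) -> float:
    n, m = len(p), len(q)
    d = np.linalg.norm(p[:, None, :] - q[None, :, :], axis=2)
    ca = np.full((n, m), np.inf)
    ca[0, 0] = d[0, 0]
    for i in range(n):
        for j in range(m):
            if i == j == 0:
                continue
            prev = min(
                ca[i - 1, j] if i > 0 else np.inf,
                ca[i, j - 1] if j > 0 else np.inf,
                ca[i - 1, j - 1] if i > 0 and j > 0 else np.inf,
            )
            ca[i, j] = max(prev, d[i, j])
    return float(ca[-1, -1])


def _dtw(p: np.ndarray, q: np.ndarray) -> float:
    n, m = len(p), len(q)
    d = np.linalg.norm(p[:, None, :] - q[None, :, :], axis=2)
    acc = np.full((n, m), np.inf)
    acc[0, 0] = d[0, 0]
    for i in range(n):
        for j in range(m):
            if i == j == 0:
                continue
            prev = min(
                acc[i - 1, j] if i > 0 else np.inf,
                acc[i, j - 1] if j > 0 else np.inf,
                acc[i - 1, j - 1] if i > 0 and j > 0 else np.inf,
            )
            acc[i, j] = d[i, j] + prev
    return float(acc[-1, -1])


def _arc_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _normalize_arc(pts: np.ndarray) -> np.ndarray:
    pts = pts - pts[0]
    length = _arc_length(pts)
    return pts if length == 0 else pts / length


def curve_distance(a, b, metric: str, x: np.ndarray | None = None) -> float:
    """Distance between two equal-length curves under a named metric."""
    ya = a.values if isinstance(a, DiurnalCurve) else np.asarray(a, float)
    yb = b.values if isinstance(b, DiurnalCurve) else np.asarray(b, float)
    if ya.shape != yb.shape:
        raise ValueError("curves must have equal length")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric == "mae":
        return float(np.mean(np.abs(ya - yb)))
    if metric == "mse":
        return float(np.mean((ya - yb) ** 2))
    pa, pb = _as_points(ya, x), _as_points(yb, x)
    if metric == "frechet":
        return _frechet(pa, pb)
    if metric == "dtw":
        return _dtw(pa, pb)
    if metric == "area":
        xa = pa[:, 0]
        return float(np.trapezoid(np.abs(ya - yb), xa))
    if metric == "curve_length":
        return float(abs(_arc_length(pa) - _arc_length(pb)))
    # pcm: mean pointwise distance after unit-arc-length normalisation
    na, nb = _normalize_arc(pa), _normalize_arc(pb)
    return float(np.mean(np.linalg.norm(na - nb, axis=1)))


# ---------------------------------------------------------------------------
# Harmonic-count selection
# ---------------------------------------------------------------------------

def distance_table(curve, m_range=(1, 4), metrics=METRICS) -> pd.DataFrame:
    """Distances between a curve and its top-m reconstructions.

    Rows cover m from ``m_range[0] - 1`` (needed by the elbow differences)
    to ``m_range[1] + 1``.
    """
    lo, hi = m_range
    if not 1 <= lo <= hi <= MAX_HARMONIC:
        raise ValueError("m_range must satisfy 1 <= lo <= hi <= 48")
    model = dft(curve)
    values = curve.values if isinstance(curve, DiurnalCurve) else np.asarray(curve, float)
    rows = []
    for m in range(max(lo - 1, 0), min(hi + 1, MAX_HARMONIC) + 1):
        if m == 0:
            recon = np.full(N_BINS, model.dc_level)
        else:
            recon = reconstruct_top_m(model, m).values
        for metric in metrics:
            rows.append({"metric": metric, "m": m,
                         "distance": curve_distance(values, recon, metric)})
    return pd.DataFrame(rows)


def select_m(curve, m_range=(1, 4), metrics=METRICS,
             return_votes: bool = False):
    """Elbow rule for the number of harmonics to keep.

    Per metric, the improvement Delta(m) = D(m-1) - D(m) is computed; the
    metric votes for the smallest m in range whose following improvement
    is smaller (the elbow), falling back to the largest m in range.  The
    final m is the smallest member of the modal vote set.
    """
    table = distance_table(curve, m_range, metrics)
    lo, hi = m_range
    votes = {}
    for metric in metrics:
        sub = table[table.metric == metric].set_index("m")["distance"]
        vote = hi
        for m in range(lo, hi + 1):
            delta_here = sub.get(m - 1, np.nan) - sub[m]
            delta_next = sub[m] - sub.get(m + 1, np.nan)
            if np.isfinite(delta_next) and delta_next < delta_here:
                vote = m
                break
        votes[metric] = vote
    counts = pd.Series(list(votes.values())).value_counts()
    top = counts[counts == counts.max()].index
    chosen = int(min(top))
    if return_votes:
        return chosen, votes, table
    return chosen
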