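"""Heightened-activity windows, inferred waking, and peak location.

The 16 continuous hours of highest aggregated activity serve as a coarse
proxy for a cluster's habitual waking period; the complementary interval
is interpreted as prolonged wakefulness.  Curves can be rotated to an
hours-since-waking axis for cross-cluster comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activity import BIN_HOURS, BIN_STARTS, DiurnalCurve, N_BINS

DEFAULT_WAKING_HOURS = 16.0


def hour_shift(t: float, n: float) -> float:
    """Time of day n hours past t, wrapping around midnight."""
    return (t + n) % 24.0


def in_window(s: float, t: float, n: float, include_start: bool = False) -> bool:
    """Whether time point s falls within n hours past t.

    With ``include_start=False`` both boundaries are strict (the printed
    case split); binning uses ``include_start=True`` so a window of n
    hours covers exactly 4n quarter-hour bins.
    """
    end = hour_shift(t, n)
    if include_start and s == t:
        return True
    if t < end:
        return t < s < end
    return s > t or s < end


@dataclass
class ActivityWindow:
    """A circular heightened-activity window [onset, onset + n)."""

    onset: float
    n: float = DEFAULT_WAKING_HOURS

    def __post_init__(self):
        if not 0 <= self.onset < 24:
            raise ValueError("onset must lie in [0, 24)")
        if not 0 < self.n <= 24:
            raise ValueError("window length must lie in (0, 24]")

    @property
    def end(self) -> float:
        return hour_shift(self.onset, self.n)

    def bin_indices(self) -> np.ndarray:
        """Indices of the 4n bins whose start lies in [onset, onset + n)."""
        start = int(round(self.onset / BIN_HOURS))
        length = int(round(self.n / BIN_HOURS))
        return (start + np.arange(length)) % N_BINS

    def complement_bin_indices(self) -> np.ndarray:
        start = int(round(self.end / BIN_HOURS))
        length = N_BINS - int(round(self.n / BIN_HOURS))
        return (start + np.arange(length)) % N_BINS


def heightened_onset(curve, n: float = DEFAULT_WAKING_HOURS) -> ActivityWindow:
    """Onset maximising the circular sum of curve values over the window.

    Computed for every quarter-hour candidate onset via a circular
    rolling sum; ties are broken toward the earliest onset after 0:00.
    """
    values = curve.values if isinstance(curve, DiurnalCurve) else np.asarray(curve, float)
    if values.shape != (N_BINS,):
        raise ValueError(f"need {N_BINS} values")
    if np.all(values == 0):
        raise ValueError("window undefined for an all-zero curve")
    length = int(round(n / BIN_HOURS))
    if not 0 < length <= N_BINS:
        raise ValueError("n must lie in (0, 24]")
    doubled = np.concatenate([values, values])
    # direct per-onset sums (a running difference would break exact ties
    # between equal windows through floating-point cancellation)
    window_sums = np.array([doubled[s:s + length].sum()
                            for s in range(N_BINS)])
    onset_bin = int(np.argmax(window_sums))  # argmax takes the first = earliest
    return ActivityWindow(onset=float(BIN_STARTS[onset_bin]), n=float(n))


def prolonged_wakefulness(window: ActivityWindow) -> tuple[float, float]:
    """Complement interval [end, onset), of length 24 - n hours."""
    return (window.end, window.onset)


def align_by_waking(curve, window: ActivityWindow) -> DiurnalCurve:
    """Rotate a curve so position 0 is the inferred waking onset."""
    values = curve.values if isinstance(curve, DiurnalCurve) else np.asarray(curve, float)
    shift = int(round(window.onset / BIN_HOURS))
    rolled = np.roll(values, -shift)
    if isinstance(curve, DiurnalCurve):
        return DiurnalCurve(rolled, kind=curve.kind, normalized=curve.normalized)
    return DiurnalCurve(rolled, kind="ratio")


def find_peaks(curve, k: int = 2) -> list[tuple[float, float]]:
    """Top-k circular local maxima as (bin start hour, value).

    A bin is a peak when strictly greater than both circular neighbours;
    a constant curve has none.
    """
    values = curve.values if isinstance(curve, DiurnalCurve) else np.asarray(curve, float)
    left = np.roll(values, 1)
    right = np.roll(values, -1)
    is_peak = (values > left) & (values > right)
    idx = np.nonzero(is_peak)[0]
    peaks = sorted(((float(BIN_STARTS[i]), float(values[i])) for i in idx),
                   key=lambda p: -p[1])
    return peaks[:k]
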