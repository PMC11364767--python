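"""Diurnal activity curves on the 96-bin quarter-hour grid.

Posts are binned by local civil time (Central European Time with DST by
default, the convention of the Italian data the pipeline emulates), each
user's bin counts are normalised into an activity curve (the share of the
user's posts falling in each 15-minute interval), and curves are smoothed
with a circular Gaussian window before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_BINS = 96
BIN_HOURS = 0.25
#: start hour of each 15-minute interval of the day
BIN_STARTS = np.arange(N_BINS) * BIN_HOURS
LOCAL_TZ = "Europe/Rome"

#: merged 8-category source-reliability vocabulary, in increasing Harm Score
CATEGORIES = (
    "Scientific",
    "Mainstream Media",
    "Satire",
    "Clickbait",
    "Other",
    "Political",
    "Fake and Hoax",
    "Conspiracy and Junk Science",
)
#: potentially disinformative categories (Harm Score >= 7)
DISINFORMATIVE = ("Political", "Fake and Hoax", "Conspiracy and Junk Science")


@dataclass
class DiurnalCurve:
    """A 96-bin circular curve over the day.

    ``kind`` is one of ``activity`` (nonnegative, sums to 1 when
    ``normalized``), ``count`` or ``ratio`` (values in [0, 1] where
    defined; undefined bins are NaN).
    """

    values: np.ndarray
    kind: str = "activity"
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_BINS,):
            raise ValueError(f"curve needs {N_BINS} values")
        if self.kind in ("activity", "count"):
            if not np.all(np.isfinite(self.values)):
                raise ValueError("activity/count curves must be finite")
            if np.any(self.values < -1e-12):
                raise ValueError("activity/count values must be >= 0")
        if self.kind == "activity" and self.normalized:
            if abs(self.values.sum() - 1.0) > 1e-9:
                raise ValueError("normalized activity must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_start_hour": BIN_STARTS,
                             "value": self.values})


@dataclass
class UserProfile:
    """Per-user post counts on the (bin x category) grid."""

    user_id: object
    counts: np.ndarray  # shape (96, n_categories)
    categories: tuple = CATEGORIES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_BINS, len(self.categories)):
            raise ValueError("counts must be (96, n_categories)")

    @property
    def total_posts(self) -> int:
        return int(self.counts.sum())

    def category_counts(self, names) -> np.ndarray:
        idx = [self.categories.index(n) for n in names]
        return self.counts[:, idx].sum(axis=1)


def bin_posts(posts: pd.DataFrame, tz: str = LOCAL_TZ,
              categories=CATEGORIES) -> dict:
    """Bin a post table into per-user 96 x |F| count arrays.

    ``posts`` needs columns ``user_id``, ``timestamp`` (timezone-aware)
    and ``category``.  Timestamps are converted to local civil time ``tz``
    before binning; bin index is floor(4 * local hour fraction).
    """
    ts = posts["timestamp"]
    if not isinstance(ts.dtype, pd.DatetimeTZDtype):
        raise ValueError("timestamps must be timezone-aware; "
                         "localize them before binning")
    local = ts.dt.tz_convert(tz)
    hour = (local.dt.hour + local.dt.minute / 60.0
            + local.dt.second / 3600.0 + local.dt.microsecond / 3.6e9)
    bins = np.floor(hour * 4).astype(int) % N_BINS
    cat_index = pd.Categorical(posts["category"], categories=categories)
    if cat_index.isna().any():
        bad = posts["category"][np.asarray(cat_index.codes) == -1].iloc[0]
        raise ValueError(f"unknown category {bad!r}")
    frame = pd.DataFrame({
        "user_id": posts["user_id"].to_numpy(),
        "bin": bins.to_numpy(),
        "cat": cat_index.codes,
    })
    profiles = {}
    for uid, grp in frame.groupby("user_id", sort=True):
        counts = np.zeros((N_BINS, len(categories)))
        np.add.at(counts, (grp["bin"].to_numpy(), grp["cat"].to_numpy()), 1.0)
        profiles[uid] = UserProfile(uid, counts, tuple(categories))
    return profiles


def user_activity(profile: UserProfile) -> DiurnalCurve:
    """Share of the user's posts in each 15-minute interval."""
    total = profile.counts.sum()
    if total <= 0:
        raise ValueError(f"user {profile.user_id!r} has no posts; "
                         "activity is undefined")
    return DiurnalCurve(profile.counts.sum(axis=1) / total,
                        kind="activity", normalized=True)


def gaussian_kernel(window_bins: int = 6, sigma_bins: float = 3.0) -> np.ndarray:
    """Normalised Gaussian taps spanning +-window_bins/2 around the centre.

    A 6-bin (90-minute) window yields 7 symmetric taps at offsets -3..3.
    """
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    if sigma_bins <= 0:
        raise ValueError("sigma must be positive")
    half = window_bins // 2
    offsets = np.arange(-half, window_bins - half)
    if window_bins % 2 == 0:  # symmetric taps for an even-width window
        offsets = np.arange(-half, half + 1)
    w = np.exp(-0.5 * (offsets / sigma_bins) ** 2)
    return w / w.sum()


def smooth_circular(curve: DiurnalCurve, window_bins: int = 6,
                    sigma_bins: float = 3.0) -> DiurnalCurve:
    """Circular (wrap-around-midnight) Gaussian rolling average.

    The kernel is normalised, so a constant curve is a fixed point and the
    total mass of the curve is preserved.
    """
    kernel = gaussian_kernel(window_bins, sigma_bins)
    half = kernel.size // 2
    padded = np.concatenate([curve.values[-half:], curve.values,
                             curve.values[:half]])
    smoothed = np.convolve(padded, kernel, mode="valid")
    return DiurnalCurve(smoothed, kind=curve.kind,
                        normalized=curve.normalized)


def smooth_values(values: np.ndarray, window_bins: int = 6,
                  sigma_bins: float = 3.0) -> np.ndarray:
    """Circular Gaussian smoothing of a bare 96-vector (NaN-free)."""
    return smooth_circular(DiurnalCurve(values, kind="count"),
                           window_bins, sigma_bins).values


def cluster_activity(curves: dict, members) -> DiurnalCurve:
    """Unweighted mean of the members' normalised activity curves."""
    members = list(members)
    if not members:
        raise ValueError("cluster is empty")
    stack = np.stack([curves[m].values for m in members])
    return DiurnalCurve(stack.mean(axis=0), kind="activity", normalized=True)


def disinformative_activity(profiles: dict, members,
                            disinformative=DISINFORMATIVE,
                            window_bins: int = 6,
                            sigma_bins: float = 6.0,
                            smooth: bool = True) -> DiurnalCurve:
    """Cluster activity computed from disinformative posts only.

    Each member's curve is normalised by their own disinformative total;
    members without any disinformative post are excluded (the per-user
    share is undefined for them).  ``sigma_bins`` defaults to 6 for this
    restricted signal.
    """
    rows = []
    for m in members:
        counts = profiles[m].category_counts(disinformative)
        total = counts.sum()
        if total > 0:
            rows.append(counts / total)
    if not rows:
        raise ValueError("no member has any disinformative post")
    mean = np.stack(rows).mean(axis=0)
    if smooth:
        mean = smooth_values(mean, window_bins, sigma_bins)
    return DiurnalCurve(mean, kind="activity", normalized=abs(mean.sum() - 1) < 1e-9)
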