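"""Harm-Score classification and content-type ratio curves.

Sources fall into nine categories of increasing Harm Score; messages
whose source category scores 7 or higher (politically biased, fake or
hoax, conspiracy or junk science) are treated as potentially
disinformative.  Ratios are computed per user and 15-minute bin against
all classified content excluding the unclassifiable "Other" bucket
(which absorbs "Shadow"), then averaged per cluster, smoothed, and
harmonically truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as cstats
from .activity import (
    BIN_STARTS,
    CATEGORIES,
    DISINFORMATIVE,
    DiurnalCurve,
    N_BINS,
    UserProfile,
    smooth_values,
)
from .harmonics import dft, reconstruct_top_m, select_m

#: nine-category scheme with ordinal Harm Scores; Shadow is merged into
#: Other for analysis, both are excluded from the classified set F^K
HARM_SCORES = {
    "Scientific": 1,
    "Mainstream Media": 2,
    "Satire": 3,
    "Clickbait": 4,
    "Other": 5,
    "Shadow": 6,
    "Political": 7,
    "Fake and Hoax": 8,
    "Conspiracy and Junk Science": 9,
}
HARM_THRESHOLD = 7
#: classified categories (denominator of every ratio)
CLASSIFIED = tuple(c for c in CATEGORIES if c != "Other")


def classify_harm(category: str) -> tuple[int, bool]:
    """(harm score, potentially-disinformative flag) for a category."""
    if category not in HARM_SCORES:
        raise ValueError(f"unknown category {category!r}")
    score = HARM_SCORES[category]
    return score, score >= HARM_THRESHOLD


def merge_shadow(category: str) -> str:
    """Map the raw nine-category scheme onto the merged eight."""
    return "Other" if category == "Shadow" else category


def user_ratio_curve(profile: UserProfile,
                     target=DISINFORMATIVE) -> np.ndarray:
    """Per-bin ratio of target-category posts among classified posts.

    Bins without classified posts are NaN (undefined), not zero.
    """
    target = tuple(target)
    if not set(target) <= set(CLASSIFIED):
        raise ValueError("target categories must be classified (not 'Other')")
    num = profile.category_counts(target)
    den = profile.category_counts(CLASSIFIED)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    return ratio


def user_overall_ratio(profile: UserProfile,
                       target=DISINFORMATIVE) -> float:
    """Whole-day ratio of target posts among the user's classified posts."""
    num = profile.category_counts(tuple(target)).sum()
    den = profile.category_counts(CLASSIFIED).sum()
    return float(num / den) if den > 0 else float("nan")


def cluster_ratio_curve(profiles: dict, members,
                        target=DISINFORMATIVE,
                        presmooth: bool = False,
                        window_bins: int = 6,
                        sigma_bins: float = 3.0) -> DiurnalCurve:
    """Unweighted mean of per-user ratio curves over cluster members.

    Undefined per-user bins are masked out of the mean (zero-filling
    would bias the cluster ratio toward 0).  A bin where no member has a
    defined ratio stays NaN.  With ``presmooth`` each user curve receives
    a circular Gaussian pass first (undefined bins interpolated
    circularly before smoothing and re-masked after).
    """
    rows = []
    for m in members:
        r = user_ratio_curve(profiles[m], target)
        if presmooth and np.any(np.isfinite(r)):
            defined = np.isfinite(r)
            filled = circular_interpolate(r)
            r = smooth_values(filled, window_bins, sigma_bins)
            r[~defined] = np.nan
        rows.append(r)
    if not rows:
        raise ValueError("cluster is empty")
    stack = np.vstack(rows)
    defined = np.isfinite(stack)
    n_def = defined.sum(axis=0)
    sums = np.where(defined, stack, 0.0).sum(axis=0)
    mean = np.where(n_def > 0, sums / np.maximum(n_def, 1), np.nan)
    return DiurnalCurve(mean, kind="ratio")


def circular_interpolate(values: np.ndarray) -> np.ndarray:
    """Fill NaN bins by linear interpolation on the circle."""
    values = np.asarray(values, dtype=float)
    defined = np.isfinite(values)
    if defined.all():
        return values.copy()
    if not defined.any():
        raise ValueError("cannot interpolate an all-undefined curve")
    idx = np.nonzero(defined)[0]
    # unwrap by tripling the domain so interpolation crosses midnight
    x = np.concatenate([idx - N_BINS, idx, idx + N_BINS])
    y = np.tile(values[idx], 3)
    out = values.copy()
    missing = np.nonzero(~defined)[0]
    out[missing] = np.interp(missing, x, y)
    return out


def smooth_ratio(profiles: dict, members, target=DISINFORMATIVE,
                 m_range=(1, 4), window_bins: int = 6,
                 sigma_bins: float = 3.0):
    """Coarse and harmonically smoothed cluster ratio curves.

    Pipeline: per-user circular Gaussian smoothing of ratio curves ->
    masked cluster mean (the "coarse" curve) -> circular interpolation of
    any residual undefined bins -> DFT truncation at the elbow-selected
    m (the "smooth" curve R).  Returns (coarse, smooth, chosen_m,
    interpolated_bin_count).
    """
    coarse = cluster_ratio_curve(profiles, members, target,
                                 presmooth=True, window_bins=window_bins,
                                 sigma_bins=sigma_bins)
    defined = np.isfinite(coarse.values)
    if not defined.any():
        raise ValueError("all bins undefined for this cluster ratio")
    filled = circular_interpolate(coarse.values)
    m = select_m(DiurnalCurve(filled, kind="ratio"), m_range=m_range)
    smooth = reconstruct_top_m(dft(DiurnalCurve(filled, kind="ratio")), m)
    return coarse, smooth, m, int(np.sum(~defined))


def susceptibility_times(smooth: DiurnalCurve) -> np.ndarray:
    """Bins where the smoothed ratio strictly exceeds its third quartile."""
    values = smooth.values
    if not np.all(np.isfinite(values)):
        raise ValueError("susceptibility needs a fully defined curve")
    q3 = np.percentile(values, 75)  # linear interpolation of order stats
    return np.nonzero(values > q3)[0]


def posts_vs_ratio_correlation(profiles: dict, members=None,
                               target=DISINFORMATIVE) -> cstats.StatResult:
    """Spearman correlation of per-user total posts vs overall ratio."""
    members = list(profiles if members is None else members)
    totals, ratios = [], []
    for m in members:
        r = user_overall_ratio(profiles[m], target)
        if np.isfinite(r):
            totals.append(profiles[m].total_posts)
            ratios.append(r)
    if len(totals) < 3:
        raise ValueError("need at least 3 users with a defined ratio")
    return cstats.spearman(totals, ratios)


def activity_ratio_correlation(activity_curve, ratio_curve) -> cstats.StatResult:
    """Spearman correlation across the 96 bins of activity vs ratio.

    Undefined ratio bins are dropped pairwise; the retained count is
    reported in the result.
    """
    a = activity_curve.values if isinstance(activity_curve, DiurnalCurve) \
        else np.asarray(activity_curve, float)
    r = ratio_curve.values if isinstance(ratio_curve, DiurnalCurve) \
        else np.asarray(ratio_curve, float)
    keep = np.isfinite(a) & np.isfinite(r)
    res = cstats.spearman(a[keep], r[keep])
    res.extra["bins_used"] = int(keep.sum())
    return res
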