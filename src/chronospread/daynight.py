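"""Day/night partitions of the diurnal grid and the comparisons built on
them.

Three definitions of "day" are supported: fixed clock borders derived
from annual sun times, actual daylight (geometric sunrise to sunset,
sampled on the first day of each month), and the inferred waking window.
A safety margin of s hours is excluded on either side of every border
before day and night ratio distributions are compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from . import stats as cstats
from .activity import BIN_HOURS, BIN_STARTS, LOCAL_TZ, N_BINS
from .ratios import CLASSIFIED, DISINFORMATIVE, user_overall_ratio
from .rhythm import ActivityWindow

#: geographic centre of the Italian peninsula, used when a user gives no
#: coordinates
ITALY_CENTROID = (42.5, 12.5)
#: solar altitude at geometric sunrise/sunset (refraction + solar disc)
SUN_ALTITUDE_DEG = -0.833
DEFAULT_MARGIN_HOURS = 1.0


# ---------------------------------------------------------------------------
# Solar geometry (NOAA solar position equations)
# ---------------------------------------------------------------------------

def _solar_parameters(day_of_year: int, hour_utc: float = 12.0):
    g = 2.0 * math.pi / 365.0 * (day_of_year - 1 + (hour_utc - 12.0) / 24.0)
    eqtime = 229.18 * (0.000075 + 0.001868 * math.cos(g)
                       - 0.032077 * math.sin(g) - 0.014615 * math.cos(2 * g)
                       - 0.040849 * math.sin(2 * g))
    decl = (0.006918 - 0.399912 * math.cos(g) + 0.070257 * math.sin(g)
            - 0.006758 * math.cos(2 * g) + 0.000907 * math.sin(2 * g)
            - 0.002697 * math.cos(3 * g) + 0.00148 * math.sin(3 * g))
    return eqtime, decl


def solar_times(lat: float, lon: float, d: date,
                tz: str = LOCAL_TZ) -> tuple[datetime, datetime]:
    """Geometric sunrise and sunset in local civil time.

    Zenith 90.833 degrees (standard refraction plus solar-disc radius).
    Polar day/night conditions are unsupported and raise.
    """
    if abs(lat) >= 66.0:
        raise ValueError("polar latitudes are not supported")
    eqtime, decl = _solar_parameters(d.timetuple().tm_yday)
    latr = math.radians(lat)
    zen = math.radians(90.0 - SUN_ALTITUDE_DEG)
    cos_ha = (math.cos(zen) / (math.cos(latr) * math.cos(decl))
              - math.tan(latr) * math.tan(decl))
    if not -1.0 < cos_ha < 1.0:
        raise ValueError("sun does not rise/set on this date at this latitude")
    ha = math.degrees(math.acos(cos_ha))
    rise_min = 720.0 - 4.0 * (lon + ha) - eqtime
    set_min = 720.0 - 4.0 * (lon - ha) - eqtime
    base = datetime(d.year, d.month, d.day, tzinfo=timezone.utc)
    tzinfo = ZoneInfo(tz)
    return (base + timedelta(minutes=rise_min)).astimezone(tzinfo), \
           (base + timedelta(minutes=set_min)).astimezone(tzinfo)


def _local_hour(dt: datetime) -> float:
    return dt.hour + dt.minute / 60.0 + dt.second / 3600.0


def _round_quarter(hour: float) -> float:
    return round(hour * 4.0) / 4.0


def monthly_sun_hours(lat: float, lon: float, year: int,
                      tz: str = LOCAL_TZ) -> pd.DataFrame:
    """Sunrise/sunset local hours on the first day of each month."""
    rows = []
    for month in range(1, 13):
        rise, sset = solar_times(lat, lon, date(year, month, 1), tz)
        rows.append({"month": month, "sunrise": _local_hour(rise),
                     "sunset": _local_hour(sset)})
    return pd.DataFrame(rows)


def clock_day_borders(lat: float = ITALY_CENTROID[0],
                      lon: float = ITALY_CENTROID[1],
                      year: int = 2020, tz: str = LOCAL_TZ,
                      method: str = "midrange") -> tuple[float, float]:
    """Fixed day borders from annual sun times, rounded to quarter hours.

    ``method="midrange"`` (default) takes the midpoint between the annual
    extremes of the monthly first-day sunrise (resp. sunset) times - the
    centre of the seasonal swing; ``method="mean"`` takes the arithmetic
    mean over the twelve monthly values.  At the Italian centroid the
    midrange convention reproduces the 6:30 / 18:45 borders used for the
    day-by-clock definition.
    """
    table = monthly_sun_hours(lat, lon, year, tz)
    if method == "midrange":
        rise = (table.sunrise.min() + table.sunrise.max()) / 2.0
        sset = (table.sunset.min() + table.sunset.max()) / 2.0
    elif method == "mean":
        rise = table.sunrise.mean()
        sset = table.sunset.mean()
    else:
        raise ValueError("method must be 'midrange' or 'mean'")
    return _round_quarter(rise), _round_quarter(sset)


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------

@dataclass
class DayNightPartition:
    """Per-bin labels {day, night, excluded} under one definition.

    ``labels`` has shape (96,) for the clock and waking definitions and
    (12, 96) for the daylight definition (one row per month).
    """

    definition: str
    labels: np.ndarray
    margin: float
    params: dict = field(default_factory=dict)

    def bins(self, label: str, month: int | None = None) -> np.ndarray:
        if self.labels.ndim == 1:
            return np.nonzero(self.labels == label)[0]
        if month is None:
            raise ValueError("daylight partition needs a month")
        return np.nonzero(self.labels[month - 1] == label)[0]


def _interval_labels(day_start: float, day_end: float, s: float) -> np.ndarray:
    """Labels for day [start+s, end-s) and night [end+s, start-s), both
    half-open on the circular quarter-hour grid."""
    day_len = (day_end - day_start) % 24.0
    night_len = 24.0 - day_len
    if 2 * s >= day_len or 2 * s >= night_len:
        raise ValueError("safety margin leaves an empty day or night interval")
    day_lo, day_hi = (day_start + s) % 24, (day_end - s) % 24
    night_lo, night_hi = (day_end + s) % 24, (day_start - s) % 24
    labels = np.full(N_BINS, "excluded", dtype=object)

    def mark(lo, hi, tag):
        for i, t in enumerate(BIN_STARTS):
            if (lo < hi and lo <= t < hi) or (lo >= hi and (t >= lo or t < hi)):
                labels[i] = tag

    mark(day_lo, day_hi, "day")
    mark(night_lo, night_hi, "night")
    return labels


def partition(definition: str, s: float = DEFAULT_MARGIN_HOURS,
              borders: tuple[float, float] | None = None,
              window: ActivityWindow | None = None,
              lat: float = ITALY_CENTROID[0], lon: float = ITALY_CENTROID[1],
              year: int = 2020, tz: str = LOCAL_TZ) -> DayNightPartition:
    """Build a day/night partition under one of the three definitions."""
    if s < 0:
        raise ValueError("margin must be nonnegative")
    if definition == "clock":
        if borders is None:
            borders = clock_day_borders(lat, lon, year, tz)
        labels = _interval_labels(borders[0], borders[1], s)
        return DayNightPartition("clock", labels, s, {"borders": borders})
    if definition == "daylight":
        table = monthly_sun_hours(lat, lon, year, tz)
        rows = [_interval_labels(r.sunrise, r.sunset, s)
                for r in table.itertuples()]
        return DayNightPartition("daylight", np.stack(rows), s,
                                 {"lat": lat, "lon": lon, "year": year})
    if definition == "waking":
        if window is None:
            raise ValueError("waking definition needs an ActivityWindow")
        labels = _interval_labels(window.onset, window.end, s)
        return DayNightPartition("waking", labels, s,
                                 {"onset": window.onset, "n": window.n})
    raise ValueError("definition must be clock, daylight or waking")


# ---------------------------------------------------------------------------
# Day vs night comparison
# ---------------------------------------------------------------------------

def day_night_test(ratio_values: np.ndarray, part: DayNightPartition,
                   alternative: str = "auto",
                   month: int | None = None) -> cstats.StatResult:
    """Mann-Whitney U test of per-bin ratio values, day vs night.

    ``ratio_values`` is a 96-vector (NaN bins dropped).  With
    ``alternative="auto"`` the two-sided test is run first; if it is
    significant at 0.05 the one-tailed p in the indicated direction is
    reported along with which side is smaller, mirroring the "Less"
    column of day/night comparison tables.  Explicit ``"less"`` /
    ``"greater"`` / ``"two-sided"`` refer to the day sample.
    """
    ratio_values = np.asarray(ratio_values, dtype=float)
    day = ratio_values[part.bins("day", month)]
    night = ratio_values[part.bins("night", month)]
    day = day[np.isfinite(day)]
    night = night[np.isfinite(night)]
    if day.size == 0 or night.size == 0:
        raise ValueError("a side is empty after margin exclusion")
    if alternative != "auto":
        res = cstats.mann_whitney(day, night, alternative)
    else:
        two = cstats.mann_whitney(day, night, "two-sided")
        if two.p < 0.05:
            direction = "less" if _median_less(day, night) else "greater"
            res = cstats.mann_whitney(day, night, direction)
            res.smaller = "day" if direction == "less" else "night"
        else:
            res = two
    res.extra["definition"] = part.definition
    return res


def _median_less(a: np.ndarray, b: np.ndarray) -> bool:
    # direction from the U statistic itself: U < n1 n2 / 2 means a below b
    return cstats._u_statistic(np.asarray(a), np.asarray(b)) < a.size * b.size / 2


def cluster_ratio_comparison(curve_a: np.ndarray, curve_b: np.ndarray,
                             alternative: str = "less") -> cstats.StatResult:
    """One-sided U test whether curve_a's 96 per-bin ratios sit below
    curve_b's; undefined bins are dropped pairwise per curve."""
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    res = cstats.mann_whitney(a, b, alternative)
    res.extra["bins_used"] = (int(a.size), int(b.size))
    return res


# ---------------------------------------------------------------------------
# Lockdown comparison
# ---------------------------------------------------------------------------

def lockdown_compare(posts: pd.DataFrame, assignments: dict,
                     lockdown: tuple, names: dict | None = None,
                     tz: str = LOCAL_TZ) -> pd.DataFrame:
    """Per-cluster percent change from outside to inside the lockdown.

    Reports posts per day per user, disinformative posts per day per
    user, and the mean per-user disinformative ratio, each compared as
    (lockdown - outside) / outside * 100.  Undefined changes (zero
    outside rate) are NaN-flagged.
    """
    start = pd.Timestamp(lockdown[0]).tz_localize(tz)
    end = pd.Timestamp(lockdown[1]).tz_localize(tz)
    ts = posts["timestamp"].dt.tz_convert(tz)
    in_lock = (ts >= start) & (ts < end)
    span_days = {
        True: (end - start).days,
        False: ((ts.max().normalize() - ts.min().normalize()).days + 1
                - (end - start).days),
    }
    cluster_of = posts["user_id"].map(assignments)
    disinfo = posts["category"].isin(DISINFORMATIVE)
    classified = posts["category"].isin(CLASSIFIED)
    rows = []
    for cid in sorted(set(assignments.values()), key=str):
        sel = cluster_of == cid
        users = [u for u, c in assignments.items() if c == cid]
        n_users = len(users)
        rec = {"cluster_id": cid,
               "cluster_name": (names or {}).get(cid, str(cid))}
        rates = {}
        for lock in (True, False):
            seg = sel & (in_lock == lock)
            days = max(span_days[lock], 1)
            rates[(lock, "posts")] = seg.sum() / days / max(n_users, 1)
            rates[(lock, "disinfo")] = (seg & disinfo).sum() / days / max(n_users, 1)
            # mean per-user disinformative ratio within the period
            seg_posts = posts[seg]
            per_user = []
            for u, grp in seg_posts.groupby("user_id"):
                den = grp["category"].isin(CLASSIFIED).sum()
                if den > 0:
                    per_user.append(grp["category"].isin(DISINFORMATIVE).sum() / den)
            rates[(lock, "ratio")] = float(np.mean(per_user)) if per_user else np.nan
        for quantity, label in (("posts", "posts_per_day_user_pct"),
                                ("disinfo", "disinfo_per_day_user_pct"),
                                ("ratio", "mean_user_ratio_pct")):
            out = rates[(False, quantity)]
            inn = rates[(True, quantity)]
            rec[label] = (inn - out) / out * 100.0 if out and np.isfinite(out) \
                else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def lockdown_chi_square(posts: pd.DataFrame, assignments: dict,
                        lockdown: tuple, tz: str = LOCAL_TZ,
                        disinformative_only: bool = True) -> cstats.StatResult:
    """Chi-square on the cluster x period post-count table."""
    start = pd.Timestamp(lockdown[0]).tz_localize(tz)
    end = pd.Timestamp(lockdown[1]).tz_localize(tz)
    ts = posts["timestamp"].dt.tz_convert(tz)
    sub = posts
    if disinformative_only:
        sub = posts[posts["category"].isin(DISINFORMATIVE)]
        ts = ts[sub.index]
    in_lock = ((ts >= start) & (ts < end)).to_numpy()
    cluster_of = sub["user_id"].map(assignments).to_numpy()
    ids = sorted(set(assignments.values()), key=str)
    table = np.array([
        [np.sum((cluster_of == cid) & in_lock),
         np.sum((cluster_of == cid) & ~in_lock)]
        for cid in ids
    ])
    return cstats.chi_square(table)
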