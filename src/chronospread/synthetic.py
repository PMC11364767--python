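"""Synthetic post streams with planted diurnal and content structure.

The generator emulates the statistical shape of the restricted social
media dataset the pipeline was designed around: users split into
morning / intermediate / evening / infrequent archetypes, each with a
bimodal diurnal posting intensity (a mixture of one or two wrapped
normal components on the 24-hour circle); heavy-tailed per-user post
counts with the infrequent archetype capped below the 240-post
threshold; an 8-category source-reliability mix per archetype with the
potentially disinformative share elevated at night; and a multi-month
date span containing a lockdown sub-interval with an elevated posting
rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .activity import CATEGORIES, DISINFORMATIVE, LOCAL_TZ

ARCHETYPES = ("morning", "intermediate", "evening", "infrequent")

#: diurnal peak centres (hours), weights and wrapped-normal spreads per
#: archetype, shaped after the canonical bimodal day curves: morning
#: types peak mid-morning with an evening echo, evening types around
#: 23:00, intermediate types near noon and mid-evening, infrequent
#: posters nearly flat
DEFAULT_PEAKS = {
    "morning": ((9.5, 20.0), (0.65, 0.35), (1.8, 2.2)),
    "intermediate": ((12.0, 21.0), (0.55, 0.45), (2.2, 2.2)),
    "evening": ((23.25, 13.5), (0.6, 0.4), (2.0, 2.8)),
    "infrequent": ((12.0, 22.0), (0.5, 0.5), (5.0, 5.0)),
}

#: 8-category simplex per archetype (order = activity.CATEGORIES);
#: mainstream media dominate everywhere, "Other" is the large
#: unclassifiable bucket, evening types carry the largest and
#: infrequent posters the smallest disinformative share
DEFAULT_CATEGORY_PROBS = {
    "morning": (0.04, 0.40, 0.02, 0.04, 0.30, 0.11, 0.05, 0.04),
    "intermediate": (0.04, 0.41, 0.02, 0.04, 0.30, 0.10, 0.05, 0.04),
    "evening": (0.03, 0.33, 0.02, 0.04, 0.30, 0.15, 0.07, 0.06),
    "infrequent": (0.06, 0.44, 0.02, 0.04, 0.30, 0.08, 0.03, 0.03),
}

#: lognormal (median, sigma of log) and truncation bounds of per-user
#: post counts; the infrequent archetype is truncated above at the
#: 240-post threshold minus one, the others below at the threshold
DEFAULT_POST_COUNTS = {
    "morning": (700.0, 0.8, 240, None),
    "intermediate": (700.0, 0.8, 240, None),
    "evening": (700.0, 0.8, 240, None),
    "infrequent": (40.0, 1.0, 1, 239),
}


@dataclass
class SyntheticConfig:
    n_users: int = 200
    cluster_proportions: tuple = (0.18, 0.22, 0.15, 0.45)
    peak_times: dict = field(default_factory=lambda: dict(DEFAULT_PEAKS))
    category_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS))
    posts_per_user: dict = field(
        default_factory=lambda: dict(DEFAULT_POST_COUNTS))
    night_disinfo_boost: float = 1.5
    night_interval: tuple = (22.5, 6.5)
    date_span: tuple = ("2020-01-22", "2022-08-01")
    lockdown: tuple | None = ("2020-03-09", "2020-05-18")
    lockdown_rate_multiplier: float = 1.8
    tz: str = LOCAL_TZ
    seed: int = 0

    def __post_init__(self):
        props = np.asarray(self.cluster_proportions, dtype=float)
        if props.size != len(ARCHETYPES) or abs(props.sum() - 1) > 1e-9 \
                or np.any(props < 0):
            raise ValueError("cluster_proportions must be a 4-simplex")
        if self.n_users < 0:
            raise ValueError("n_users must be >= 0")
        for arch, (centres, weights, sigmas) in self.peak_times.items():
            if not all(0 <= c < 24 for c in centres):
                raise ValueError(f"{arch}: peak centres must lie in [0, 24)")
            if abs(sum(weights) - 1) > 1e-9:
                raise ValueError(f"{arch}: peak weights must sum to 1")
        for arch, probs in self.category_probs.items():
            p = np.asarray(probs, dtype=float)
            if p.size != len(CATEGORIES) or abs(p.sum() - 1) > 1e-9 \
                    or np.any(p < 0):
                raise ValueError(f"{arch}: category probs must be an "
                                 f"{len(CATEGORIES)}-simplex")
        start, end = pd.Timestamp(self.date_span[0]), pd.Timestamp(self.date_span[1])
        if not start < end:
            raise ValueError("empty date_span")
        if self.lockdown is not None:
            ls, le = pd.Timestamp(self.lockdown[0]), pd.Timestamp(self.lockdown[1])
            if not (start <= ls < le <= end):
                raise ValueError("lockdown interval must lie within date_span")
        if self.night_disinfo_boost <= 0:
            raise ValueError("night_disinfo_boost must be positive")

    def to_yaml(self) -> str:
        data = asdict(self)
        return yaml.safe_dump(data, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticConfig":
        data = yaml.safe_load(text)
        for key in ("peak_times", "category_probs", "posts_per_user"):
            if key in data:
                data[key] = {k: tuple(tuple(x) if isinstance(x, list) else x
                                      for x in v) if isinstance(v, list) else v
                             for k, v in data[key].items()}
        for key in ("cluster_proportions", "night_interval", "date_span",
                    "lockdown"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class UserSpec:
    user_id: str
    archetype: str
    target_posts: int
    peaks: tuple          # (centres, weights, sigmas)
    category_probs: np.ndarray


def generate_users(config: SyntheticConfig) -> list[UserSpec]:
    """Draw user archetypes, target post counts and per-user parameters."""
    rng = np.random.default_rng(config.seed)
    users = []
    arch_idx = rng.choice(len(ARCHETYPES), size=config.n_users,
                          p=config.cluster_proportions)
    for i in range(config.n_users):
        arch = ARCHETYPES[arch_idx[i]]
        median, sigma, lower, upper = config.posts_per_user[arch]
        count = _truncated_lognormal(rng, median, sigma, lower, upper)
        users.append(UserSpec(
            user_id=f"u{i:05d}",
            archetype=arch,
            target_posts=count,
            peaks=config.peak_times[arch],
            category_probs=np.asarray(config.category_probs[arch], float),
        ))
    return users


def _truncated_lognormal(rng, median, sigma, lower, upper) -> int:
    for _ in range(1000):
        value = int(round(rng.lognormal(np.log(median), sigma)))
        if (lower is None or value >= lower) and \
                (upper is None or value <= upper):
            return max(value, 1)
    # distribution badly mismatched with the bounds; clamp
    return int(np.clip(median, lower or 1, upper or np.inf))


def _is_night(hours: np.ndarray, interval: tuple) -> np.ndarray:
    lo, hi = interval
    if lo <= hi:
        return (hours >= lo) & (hours < hi)
    return (hours >= lo) | (hours < hi)


def generate_posts(users: list[UserSpec],
                   config: SyntheticConfig) -> pd.DataFrame:
    """Generate the timestamped post table for a set of user specs.

    Per post: the calendar day is uniform over the date span with
    lockdown days upweighted by the rate multiplier; the time of day is
    drawn from the user's wrapped-normal mixture; the category from the
    archetype simplex, with the disinformative share multiplied by
    ``night_disinfo_boost`` (renormalised) inside the night interval.
    """
    rng = np.random.default_rng(None if config.seed is None
                                else config.seed + 1)
    start = pd.Timestamp(config.date_span[0])
    end = pd.Timestamp(config.date_span[1])
    days = pd.date_range(start, end, freq="D", inclusive="left")
    day_weights = np.ones(len(days))
    if config.lockdown is not None:
        ls, le = pd.Timestamp(config.lockdown[0]), pd.Timestamp(config.lockdown[1])
        in_lock = (days >= ls) & (days < le)
        day_weights[in_lock] = config.lockdown_rate_multiplier
    day_weights = day_weights / day_weights.sum()
    disinfo_mask = np.array([c in DISINFORMATIVE for c in CATEGORIES])

    frames = []
    for user in users:
        n = user.target_posts
        centres, weights, sigmas = user.peaks
        comp = rng.choice(len(centres), size=n, p=weights)
        hours = np.asarray([
            rng.normal(centres[c], sigmas[c]) for c in comp
        ]) % 24.0
        day_idx = rng.choice(len(days), size=n, p=day_weights)
        night = _is_night(hours, config.night_interval)
        probs_day = user.category_probs
        probs_night = probs_day.copy()
        probs_night[disinfo_mask] *= config.night_disinfo_boost
        probs_night /= probs_night.sum()
        cats = np.empty(n, dtype=int)
        if night.any():
            cats[night] = rng.choice(len(CATEGORIES), size=int(night.sum()),
                                     p=probs_night)
        if (~night).any():
            cats[~night] = rng.choice(len(CATEGORIES), size=int((~night).sum()),
                                      p=probs_day)
        frames.append(pd.DataFrame({
            "user_id": user.user_id,
            "day": days[day_idx],
            "hour": hours,
            "category": [CATEGORIES[c] for c in cats],
        }))
    if not frames:
        return _empty_posts()
    table = pd.concat(frames, ignore_index=True)
    naive = table["day"] + pd.to_timedelta(table["hour"], unit="h")
    # snap into valid local civil time across DST transitions
    table["timestamp"] = naive.dt.tz_localize(
        config.tz, nonexistent="shift_forward", ambiguous=False)
    table["lat"] = np.nan
    table["lon"] = np.nan
    out = table[["user_id", "timestamp", "category", "lat", "lon"]]
    return out.sort_values(["user_id", "timestamp"], kind="stable") \
              .reset_index(drop=True)


def _empty_posts() -> pd.DataFrame:
    return pd.DataFrame({
        "user_id": pd.Series(dtype=str),
        "timestamp": pd.Series(dtype="datetime64[ns, UTC]"),
        "category": pd.Series(dtype=str),
        "lat": pd.Series(dtype=float),
        "lon": pd.Series(dtype=float),
    })


def generate(config: SyntheticConfig):
    """Users and posts in one call; returns (users, posts)."""
    users = generate_users(config)
    return users, generate_posts(users, config)


# ---------------------------------------------------------------------------
# Post-table I/O (CSV with ISO-8601 timestamps carrying a UTC offset)
# ---------------------------------------------------------------------------

POST_COLUMNS = ("user_id", "timestamp", "category", "lat", "lon")


def write_posts(posts: pd.DataFrame, path) -> None:
    out = posts.copy()
    out["timestamp"] = out["timestamp"].map(
        lambda t: t.isoformat() if pd.notna(t) else "")
    out.to_csv(path, index=False, columns=list(POST_COLUMNS))


def read_posts(path, tz: str = LOCAL_TZ) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype={"user_id": str, "category": str})
    missing = set(POST_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"post table misses columns {sorted(missing)}")
    bad = ~raw["category"].isin(CATEGORIES)
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
        raise ValueError(
            f"line {line}: unknown category {raw['category'][bad].iloc[0]!r}")
    try:
        ts = pd.to_datetime(raw["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable timestamp: {exc}") from exc
    if ts.isna().any() and len(raw):
        line = int(ts.index[ts.isna()][0]) + 2
        raise ValueError(f"line {line}: missing or naive timestamp")
    raw["timestamp"] = ts.dt.tz_convert(tz)
    return raw[list(POST_COLUMNS)]
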