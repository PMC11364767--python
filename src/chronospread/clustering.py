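"""Archetype clustering of smoothed per-user activity curves.

Infrequent posters (fewer than 240 posts by default) are set aside as
their own archetype; the remaining users' 96-bin smoothed activity curves
are clustered with k-means (k = 3 in the reference configuration), and
clusters are named morning / intermediate / evening from the clock time
of their activity peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .activity import BIN_HOURS, BIN_STARTS, DiurnalCurve

INFREQUENT_THRESHOLD = 240
INFREQUENT_ID = -1
MORNING_BEFORE = 12.0   # peak before noon -> morning type
EVENING_AFTER = 20.0    # peak after 8 pm -> evening type


@dataclass
class ClusterModel:
    assignments: dict           # user_id -> cluster id (INFREQUENT_ID reserved)
    centroids: np.ndarray       # (k, 96)
    k: int
    validity: dict = field(default_factory=dict)
    names: dict = field(default_factory=dict)
    infrequent_threshold: int = INFREQUENT_THRESHOLD
    inertia: float = float("nan")

    def members(self, cluster_id) -> list:
        return [u for u, c in self.assignments.items() if c == cluster_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"user_id": u, "cluster_id": c,
              "cluster_name": self.names.get(c, str(c))}
             for u, c in self.assignments.items()]
        )


def split_infrequent(profiles: dict, threshold: int = INFREQUENT_THRESHOLD):
    """Partition users into (frequent, infrequent) by strict total < threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    frequent, infrequent = {}, {}
    for uid, prof in profiles.items():
        (infrequent if prof.total_posts < threshold else frequent)[uid] = prof
    return frequent, infrequent


def fit_archetypes(curves: dict, k: int = 3, seed: int = 0,
                   n_restarts: int = 10) -> ClusterModel:
    """K-means over smoothed activity curves (k-means++, multiple restarts)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    users = sorted(curves, key=str)
    if len(users) < k:
        raise ValueError(f"k={k} exceeds the {len(users)} available users")
    X = np.stack([np.asarray(curves[u].values if isinstance(curves[u], DiurnalCurve)
                             else curves[u], float) for u in users])
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed)
    labels = km.fit_predict(X)
    assignments = dict(zip(users, (int(l) for l in labels)))
    return ClusterModel(assignments=assignments, centroids=km.cluster_centers_,
                        k=k, inertia=float(km.inertia_))


# ---------------------------------------------------------------------------
# Validity indices
# ---------------------------------------------------------------------------

def _pairwise_min_between(X, labels, a, b):
    da = X[labels == a]
    db = X[labels == b]
    d = np.linalg.norm(da[:, None, :] - db[None, :, :], axis=2)
    return d.min()


def _diameter(X, labels, a):
    da = X[labels == a]
    if len(da) < 2:
        return 0.0
    d = np.linalg.norm(da[:, None, :] - da[None, :, :], axis=2)
    return d.max()


def generalized_dunn(X: np.ndarray, labels: np.ndarray) -> float:
    """Dunn index: min between-cluster single-linkage distance over the
    largest cluster diameter (higher is better)."""
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters")
    min_between = min(
        _pairwise_min_between(X, labels, a, b)
        for i, a in enumerate(ids) for b in ids[i + 1:]
    )
    max_diam = max(_diameter(X, labels, a) for a in ids)
    if max_diam == 0:
        return float("inf")
    return float(min_between / max_diam)


def cop_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Context-independent optimality: per cluster, mean distance to the
    centroid over the minimal distance to a point outside the cluster,
    averaged with cluster-size weights (lower is better)."""
    ids = np.unique(labels)
    total = 0.0
    for a in ids:
        pts = X[labels == a]
        out = X[labels != a]
        if len(out) == 0:
            raise ValueError("COP needs at least 2 clusters")
        centroid = pts.mean(axis=0)
        intra = np.linalg.norm(pts - centroid, axis=1).mean()
        # for each member, nearest outside point; cluster separation is the
        # max over members of that nearest-outside distance
        d_out = np.linalg.norm(pts[:, None, :] - out[None, :, :], axis=2)
        sep = d_out.min(axis=1).max()
        total += len(pts) * (intra / sep if sep > 0 else np.inf)
    return float(total / len(X))


def validity_scores(curves: dict, seed: int = 0, k_range=range(2, 7),
                    n_restarts: int = 10, include_cop: bool = True) -> pd.DataFrame:
    """Cluster-validity indices per candidate k.

    Davies-Bouldin and COP are lower-is-better; the ``higher_is_better``
    column records the orientation so the table can be read uniformly.
    Degenerate cases (singleton clusters) yield NaN with a flag rather
    than failing.
    """
    users = sorted(curves, key=str)
    X = np.stack([np.asarray(curves[u].values if isinstance(curves[u], DiurnalCurve)
                             else curves[u], float) for u in users])
    rows = []
    for k in k_range:
        if not 2 <= k <= len(users) - 1:
            raise ValueError("k_range must lie within [2, n_users - 1]")
        model = fit_archetypes(curves, k=k, seed=seed, n_restarts=n_restarts)
        labels = np.array([model.assignments[u] for u in users])
        flags = []

        def guarded(fn, lower_is_better=False):
            try:
                return fn(X, labels), lower_is_better
            except ValueError as exc:
                flags.append(str(exc))
                return float("nan"), lower_is_better

        for name, fn, lower in (
            ("calinski_harabasz", calinski_harabasz_score, False),
            ("davies_bouldin", davies_bouldin_score, True),
            ("silhouette", silhouette_score, False),
            ("generalized_dunn", generalized_dunn, False),
        ):
            score, _ = guarded(fn, lower)
            rows.append({"k": k, "index": name, "score": score,
                         "higher_is_better": not lower,
                         "flag": "; ".join(flags) or None})
            flags.clear()
        if include_cop:
            score, _ = guarded(cop_index, True)
            rows.append({"k": k, "index": "cop", "score": score,
                         "higher_is_better": False,
                         "flag": "; ".join(flags) or None})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Naming
# ---------------------------------------------------------------------------

def name_clusters(cluster_curves: dict, morning_before: float = MORNING_BEFORE,
                  evening_after: float = EVENING_AFTER) -> dict:
    """Name clusters from the clock time of their global activity peak.

    Peak strictly before ``morning_before`` -> morning; strictly after
    ``evening_after`` -> evening; otherwise intermediate.  Two clusters
    mapping to the same name raise, reporting the peak times.
    """
    names, peaks = {}, {}
    for cid, curve in cluster_curves.items():
        values = curve.values if isinstance(curve, DiurnalCurve) else np.asarray(curve)
        peak_hour = float(BIN_STARTS[int(np.argmax(values))])
        peaks[cid] = peak_hour
        if peak_hour < morning_before:
            names[cid] = "morning"
        elif peak_hour > evening_after:
            names[cid] = "evening"
        else:
            names[cid] = "intermediate"
    assigned = list(names.values())
    if len(set(assigned)) != len(assigned):
        raise ValueError(f"ambiguous cluster names {names} for peaks {peaks}; "
                         "adjust the naming thresholds")
    return names


def name_clusters_by_rank(cluster_curves: dict) -> dict:
    """Rank-based fallback naming for exactly three clusters.

    Orders clusters by peak time on a circle cut at 4:00 (the diurnal
    activity minimum): earliest peak is morning, latest is evening, the
    middle one intermediate.  Used when the fixed-threshold rule maps two
    clusters to the same name.
    """
    if len(cluster_curves) != 3:
        raise ValueError("rank naming needs exactly 3 clusters")
    peaks = {}
    for cid, curve in cluster_curves.items():
        values = curve.values if isinstance(curve, DiurnalCurve) else np.asarray(curve)
        peaks[cid] = float(BIN_STARTS[int(np.argmax(values))])
    ordered = sorted(peaks, key=lambda c: (peaks[c] - 4.0) % 24.0)
    return {ordered[0]: "morning", ordered[1]: "intermediate",
            ordered[2]: "evening"}
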