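"""Place discovery and dwell-time analytics.

Outdoor GPS fixes carry no place identity, so frequently visited outdoor
places are discovered per user by k-means on local-frame coordinates, with
the cluster count either fixed or chosen by silhouette score. Indoor logs
already record the zone the tag is in, so indoor dwell analysis uses those
zone ids directly and never clusters.

Dwell time credits each inter-sample interval to the place of its leading
sample and normalises per user-day to percentages that sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

DEFAULT_K_MAX = 8
KMEANS_RESTARTS = 10


@dataclass
class PlaceModel:
    """A fitted per-user place model: centroids, assignments and inertia."""

    k: int
    centroids: np.ndarray          # (k, 2) local-frame metres
    assignments: np.ndarray        # per-input-point cluster id
    inertia: float
    silhouette: float | None = None

    def __post_init__(self) -> None:
        if self.k < 1 or self.centroids.shape[0] != self.k:
            raise ValueError("centroid count must equal k ≥ 1")


def fit_places(
    points: np.ndarray,
    k: int | str = "auto",
    k_max: int = DEFAULT_K_MAX,
    seed: int = 0,
    max_speed_mps: float | None = None,
    times: np.ndarray | None = None,
) -> PlaceModel:
    """Cluster local-frame coordinates into frequently visited places.

    ``k='auto'`` picks the cluster count by silhouette score over
    2..k_max; a single place (k=1) is returned only when the points are
    degenerate (fewer than 3, or all at one location), since silhouette is
    undefined for one cluster. An optional speed filter drops transit
    fixes (instantaneous speed above ``max_speed_mps``) before fitting;
    it is off by default.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] < 2:
        raise ValueError("points must be an (n, 2) coordinate array")
    if max_speed_mps is not None:
        if times is None:
            raise ValueError("speed filter needs per-point times")
        dt = np.diff(np.asarray(times, dtype=float))
        step = np.linalg.norm(np.diff(points, axis=0), axis=1)
        speed = np.divide(step, dt, out=np.zeros_like(step), where=dt > 0)
        keep = np.concatenate([[True], speed <= max_speed_mps])
        points = points[keep]

    n = points.shape[0]
    if isinstance(k, str):
        if k != "auto":
            raise ValueError(f"k must be an integer or 'auto', got {k!r}")
        return _fit_auto(points, k_max, seed)
    if k < 1:
        raise ValueError("k must be ≥ 1")
    if k > n:
        raise ValueError(f"cannot fit {k} clusters to {n} points")
    return _fit_fixed(points, int(k), seed)


def _fit_fixed(points: np.ndarray, k: int, seed: int) -> PlaceModel:
    km = KMeans(n_clusters=k, n_init=KMEANS_RESTARTS, random_state=seed)
    labels = km.fit_predict(points)
    sil = None
    if 2 <= k < len(points) and len(np.unique(labels)) > 1:
        sil = float(silhouette_score(points, labels))
    return PlaceModel(
        k=k,
        centroids=km.cluster_centers_,
        assignments=labels,
        inertia=float(km.inertia_),
        silhouette=sil,
    )


def _fit_auto(points: np.ndarray, k_max: int, seed: int) -> PlaceModel:
    n = points.shape[0]
    spread = float(np.ptp(points, axis=0).max()) if n else 0.0
    if n < 3 or spread < 1e-9:
        return _fit_fixed(points, 1, seed)
    best: PlaceModel | None = None
    for k in range(2, min(k_max, n - 1) + 1):
        model = _fit_fixed(points, k, seed)
        if model.silhouette is None:
            continue
        if best is None or model.silhouette > best.silhouette:
            best = model
    return best if best is not None else _fit_fixed(points, 1, seed)


def assign_place(model: PlaceModel, point: np.ndarray) -> int:
    """Nearest-centroid id for one point; ties resolve to the lowest id."""
    point = np.asarray(point, dtype=float)
    d = np.linalg.norm(model.centroids - point[None, :], axis=1)
    return int(np.argmin(d))  # argmin takes the first (lowest id) on ties


def _day_key(epoch: float) -> str:
    return datetime.fromtimestamp(epoch, tz=timezone.utc).strftime("%Y-%m-%d")


def dwell_percentages(
    times: Sequence[float],
    place_ids: Sequence[int],
    user_ids: Sequence[int] | int = 0,
) -> pd.DataFrame:
    """Per (user, day, place) dwell seconds and share of observed time.

    Each inter-sample interval is credited to the place of its leading
    sample; the last sample of a day contributes no interval. A day with a
    single sample credits 100% to that sample's place. Percentages are
    normalised per user-day and sum to 100.

    Returns a DataFrame with columns user_id, day, place_id, seconds,
    percent.
    """
    times = np.asarray(times, dtype=float)
    place_ids = np.asarray(place_ids)
    if np.isscalar(user_ids):
        user_ids = np.full(len(times), user_ids)
    user_ids = np.asarray(user_ids)
    if not (len(times) == len(place_ids) == len(user_ids)):
        raise ValueError("times, place_ids and user_ids must align")
    df = pd.DataFrame(
        {"t": times, "place_id": place_ids, "user_id": user_ids}
    ).sort_values(["user_id", "t"], kind="stable")
    df["day"] = [_day_key(t) for t in df["t"]]

    rows = []
    for (uid, day), grp in df.groupby(["user_id", "day"], sort=True):
        t = grp["t"].to_numpy()
        p = grp["place_id"].to_numpy()
        if len(t) == 1:
            rows.append((uid, day, p[0], 0.0, 100.0))
            continue
        if np.any(np.diff(t) < 0):
            raise ValueError("assignments must be time-sorted within a day")
        seconds: dict = {}
        for i in range(len(t) - 1):
            seconds[p[i]] = seconds.get(p[i], 0.0) + float(t[i + 1] - t[i])
        total = sum(seconds.values())
        for place, sec in sorted(seconds.items(), key=lambda kv: str(kv[0])):
            rows.append((uid, day, place, sec, 100.0 * sec / total))
    return pd.DataFrame(
        rows, columns=["user_id", "day", "place_id", "seconds", "percent"]
    )


def average_dwell(summary: pd.DataFrame) -> pd.DataFrame:
    """Mean per-day dwell percentage per (user, place) across days."""
    return (
        summary.groupby(["user_id", "place_id"], sort=True)["percent"]
        .mean()
        .reset_index()
    )


def match_centroids(
    model_a: PlaceModel, model_b: PlaceModel, max_distance: float = np.inf
) -> list[tuple[int, int, float]]:
    """Greedy cross-user place matching by centroid distance.

    Cluster ids are per-user labels; this optional helper pairs clusters of
    two users whose centroids lie within ``max_distance`` of each other,
    nearest pairs first, each cluster used at most once.
    """
    d = np.linalg.norm(
        model_a.centroids[:, None, :] - model_b.centroids[None, :, :], axis=2
    )
    pairs = sorted(
        ((float(d[i, j]), i, j) for i in range(model_a.k) for j in range(model_b.k))
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for dist, i, j in pairs:
        if dist > max_distance:
            break
        if i in used_a or j in used_b:
            continue
        matches.append((i, j, dist))
        used_a.add(i)
        used_b.add(j)
    return matches


def plot_dwell(summary: pd.DataFrame, path=None):
    """Bar plot of per-day dwell percentages per place, one panel per user."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    users = sorted(summary["user_id"].unique())
    fig, axes = plt.subplots(1, max(len(users), 1),
                             figsize=(4 * max(len(users), 1), 3), squeeze=False)
    for ax, uid in zip(axes[0], users):
        sub = summary[summary["user_id"] == uid]
        pivot = sub.pivot_table(index="day", columns="place_id",
                                values="percent", fill_value=0.0)
        pivot.plot(kind="bar", stacked=True, ax=ax, legend=False)
        ax.set_title(f"user {uid}")
        ax.set_ylabel("% of observed time")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
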