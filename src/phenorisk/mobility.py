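"""Stay-point detection, mean-shift place clustering, mobility features.

The location logger records fixes only while the phone is moving, so a
participant's trace is a series of movement episodes separated by silent
periods spent at a place.  Only the *last* fix of each episode — the point
where movement ended — is retained as a stay point.

Stay points are grouped into places with flat-kernel mean shift: every
point is repeatedly moved to the mean of the original points within a
window radius r until convergence, and points whose modes coincide form one
cluster.  The most-visited cluster is taken to be the participant's home,
and mobility features (distance from home, the share of stay points more
than 50 miles out, places visited per day, ...) are computed on the sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .io import LocationFix

__all__ = [
    "StayPoint",
    "PlaceCluster",
    "haversine_miles",
    "retain_stationary",
    "mean_shift_cluster",
    "assign_home",
    "mobility_features",
    "MOBILITY_FEATURE_NAMES",
    "EARTH_RADIUS_MILES",
]

EARTH_RADIUS_MILES = 3958.8
_EARTH_RADIUS_M = 6_371_008.8
DEFAULT_RADIUS_M = 100.0
DEFAULT_GAP_MAX_S = 300.0
FAR_FROM_HOME_MILES = 50.0


@dataclass(frozen=True)
class StayPoint:
    """Final fix of a movement episode — a location where time was spent."""

    participant_id: str
    timestamp: int
    lat: float
    lon: float

    @property
    def day(self):
        from .io import utc_day

        return utc_day(self.timestamp)


@dataclass(frozen=True)
class PlaceCluster:
    cluster_id: int
    lat: float
    lon: float
    visit_count: int
    first_visit_ts: int
    is_home: bool = False


def haversine_miles(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Great-circle distance in miles between (lat, lon) points in degrees."""
    lat1, lon1 = map(math.radians, p1)
    lat2, lon2 = map(math.radians, p2)
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = math.sin(dlat / 2.0) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_MILES * math.asin(min(1.0, math.sqrt(h)))


def retain_stationary(
    fixes: Sequence[LocationFix],
    gap_max_s: float = DEFAULT_GAP_MAX_S,
    v_min_mph: float | None = None,
) -> list[StayPoint]:
    """Keep the last fix of each movement episode.

    Consecutive fixes no more than ``gap_max_s`` apart belong to one episode
    (the logger emits fixes only while moving, so a silent gap means the
    movement ended and time was spent at the last position).  With
    ``v_min_mph`` set, a fix whose speed from the previous fix falls below
    the threshold also ends the episode; this is off by default.
    """
    out: list[StayPoint] = []
    prev: LocationFix | None = None
    for fix in fixes:
        if prev is not None:
            gap = (fix.timestamp - prev.timestamp) / 1000.0
            boundary = gap > gap_max_s
            if not boundary and v_min_mph is not None and gap > 0:
                speed = haversine_miles((prev.lat, prev.lon), (fix.lat, fix.lon)) / (gap / 3600.0)
                boundary = speed < v_min_mph
            if boundary:
                out.append(StayPoint(prev.participant_id, prev.timestamp, prev.lat, prev.lon))
        prev = fix
    if prev is not None:
        out.append(StayPoint(prev.participant_id, prev.timestamp, prev.lat, prev.lon))
    return out


def _to_planar_m(lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Equirectangular projection to meters around the trace centroid.

    Adequate at place scale (errors ≪ r for traces spanning < a few hundred
    miles); distances *reported* to users always use the haversine.
    """
    lat0, lon0 = lat.mean(), lon.mean()
    x = _EARTH_RADIUS_M * np.radians(lon - lon0) * math.cos(math.radians(lat0))
    y = _EARTH_RADIUS_M * np.radians(lat - lat0)
    return np.column_stack([x, y]), lat0, lon0


def _from_planar_m(xy: np.ndarray, lat0: float, lon0: float) -> tuple[float, float]:
    lat = lat0 + math.degrees(xy[1] / _EARTH_RADIUS_M)
    lon = lon0 + math.degrees(xy[0] / (_EARTH_RADIUS_M * math.cos(math.radians(lat0))))
    return lat, lon


def mean_shift_cluster(
    points: Sequence[StayPoint],
    radius_m: float = DEFAULT_RADIUS_M,
    tol_frac: float = 0.01,
    max_iter: int = 200,
) -> tuple[list[PlaceCluster], np.ndarray]:
    """Flat-kernel mean shift over one participant's stay points.

    Every point is iteratively replaced by the mean of the *original* points
    within ``radius_m`` of it until it moves less than ``tol_frac * radius_m``.
    Converged modes closer than ``radius_m / 2`` are merged; each point joins
    its mode's cluster.  Returns the clusters and a per-point cluster-id
    array.  Clusters are numbered by descending visit count (ties: earliest
    first visit).
    """
    if not points:
        raise ValueError("mean_shift_cluster requires at least one point")
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    lat = np.array([p.lat for p in points], dtype=float)
    lon = np.array([p.lon for p in points], dtype=float)
    X0, lat0, lon0 = _to_planar_m(lat, lon)
    X = X0.copy()
    tol = tol_frac * radius_m
    active = np.ones(len(X), dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        d2 = ((X[active, None, :] - X0[None, :, :]) ** 2).sum(axis=2)
        nbr = d2 <= radius_m**2
        # every point is its own neighbor, so each row has >=1 True
        means = (nbr[:, :, None] * X0[None, :, :]).sum(axis=1) / nbr.sum(axis=1)[:, None]
        shift = np.linalg.norm(means - X[active], axis=1)
        X[active] = means
        still = np.zeros(len(X), dtype=bool)
        still[np.flatnonzero(active)[shift >= tol]] = True
        active = still

    # merge modes within radius/2 of each other (greedy, first-come order)
    mode_xy: list[np.ndarray] = []
    assign = np.empty(len(X), dtype=int)
    for i, m in enumerate(X):
        for k, existing in enumerate(mode_xy):
            if np.linalg.norm(m - existing) < radius_m / 2.0:
                assign[i] = k
                break
        else:
            assign[i] = len(mode_xy)
            mode_xy.append(m)

    ts = np.array([p.timestamp for p in points])
    raw: list[tuple[int, int, np.ndarray]] = []  # (count, first_ts, mode)
    for k in range(len(mode_xy)):
        members = assign == k
        raw.append((int(members.sum()), int(ts[members].min()), mode_xy[k]))
    order = sorted(range(len(raw)), key=lambda k: (-raw[k][0], raw[k][1]))
    relabel = {old: new for new, old in enumerate(order)}
    clusters = []
    for old in order:
        count, first_ts, mode = raw[old]
        clat, clon = _from_planar_m(mode, lat0, lon0)
        clusters.append(
            PlaceCluster(
                cluster_id=relabel[old],
                lat=clat,
                lon=clon,
                visit_count=count,
                first_visit_ts=first_ts,
            )
        )
    assignment = np.array([relabel[a] for a in assign], dtype=int)
    return clusters, assignment


def assign_home(clusters: Iterable[PlaceCluster]) -> list[PlaceCluster]:
    """Flag the most-visited cluster as home (tie: earliest first visit)."""
    clusters = list(clusters)
    if not clusters:
        raise ValueError("no clusters to assign home among")
    home = min(clusters, key=lambda c: (-c.visit_count, c.first_visit_ts))
    return [replace(c, is_home=(c.cluster_id == home.cluster_id)) for c in clusters]


MOBILITY_FEATURE_NAMES = (
    "mean_dist_home",
    "max_dist_home",
    "frac_over_50mi",
    "places_per_day",
    "unique_places_per_day",
    "n_unique_places",
    "frac_days_away",
)


def mobility_features(
    staypoints: Sequence[StayPoint],
    clusters: Sequence[PlaceCluster],
    assignment: np.ndarray,
) -> dict[str, float]:
    """Per-participant mobility summary relative to the flagged home.

    Distances are stay-point-to-home haversine miles.  Day counts use the
    distinct UTC days with at least one stay point.
    """
    if not staypoints:
        return {name: float("nan") for name in MOBILITY_FEATURE_NAMES}
    home = next(c for c in clusters if c.is_home)
    d = np.array(
        [haversine_miles((sp.lat, sp.lon), (home.lat, home.lon)) for sp in staypoints]
    )
    days = [sp.day for sp in staypoints]
    uniq_days = sorted(set(days))
    n_days = len(uniq_days)
    per_day_clusters: dict = {}
    per_day_away: dict = {}
    for sp, cid in zip(staypoints, assignment):
        per_day_clusters.setdefault(sp.day, set()).add(int(cid))
        per_day_away.setdefault(sp.day, False)
        if cid != home.cluster_id:
            per_day_away[sp.day] = True
    return {
        "mean_dist_home": float(d.mean()),
        "max_dist_home": float(d.max()),
        "frac_over_50mi": float((d > FAR_FROM_HOME_MILES).mean()),
        "places_per_day": len(staypoints) / n_days,
        "unique_places_per_day": float(
            np.mean([len(per_day_clusters[day]) for day in uniq_days])
        ),
        "n_unique_places": float(len(clusters)),
        "frac_days_away": float(np.mean([per_day_away[day] for day in uniq_days])),
    }
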