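"""Haversine distances, stay-point detection, mean-shift places, mobility."""

import math

import numpy as np
import pytest

from phenorisk.io import LocationFix
from phenorisk.mobility import (
    EARTH_RADIUS_MILES,
    StayPoint,
    assign_home,
    haversine_miles,
    mean_shift_cluster,
    mobility_features,
    retain_stationary,
)
from tests.conftest import ts

MIN = 60_000  # ms


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine_miles((34.0, -118.0), (34.0, -118.0)) == 0.0

    def test_one_degree_equator(self):
        # closed-form arc length of 1 degree on the equator
        expected = EARTH_RADIUS_MILES * math.pi / 180.0
        assert haversine_miles((0, 0), (0, 1)) == pytest.approx(expected, rel=1e-9)

    def test_symmetric_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = (rng.uniform(-89, 89), rng.uniform(-179, 179))
            b = (rng.uniform(-89, 89), rng.uniform(-179, 179))
            assert haversine_miles(a, b) == pytest.approx(haversine_miles(b, a))
            assert haversine_miles(a, b) >= 0


def _fix(t, lat, lon):
    return LocationFix("P0", t, lat, lon)


class TestRetainStationary:
    def test_burst_then_silence_keeps_last_fix(self):
        t0 = ts(1)
        fixes = [_fix(t0 + i * MIN, 34.0 + i * 1e-4, -118.0) for i in range(5)]
        sps = retain_stationary(fixes, gap_max_s=300)
        assert len(sps) == 1
        assert sps[0].lat == pytest.approx(34.0 + 4e-4)

    def test_single_fix_is_own_episode(self):
        sps = retain_stationary([_fix(ts(1), 34.0, -118.0)])
        assert len(sps) == 1

    def test_two_bursts_two_staypoints(self):
        t0 = ts(1)
        burst1 = [_fix(t0 + i * MIN, 34.0, -118.0) for i in range(3)]
        burst2 = [_fix(t0 + 2 * 3_600_000 + i * MIN, 35.0, -118.0) for i in range(3)]
        sps = retain_stationary(burst1 + burst2, gap_max_s=300)
        assert [(sp.lat) for sp in sps] == [34.0, 35.0]

    def test_empty(self):
        assert retain_stationary([]) == []


def _blob(rng, center, n, spread_m=5.0):
    pts = []
    for i in range(n):
        dlat = rng.normal(0, spread_m) / 111_000.0
        dlon = rng.normal(0, spread_m) / 111_000.0
        pts.append(StayPoint("P0", ts(1) + i * MIN, center[0] + dlat, center[1] + dlon))
    return pts


class TestMeanShift:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(0)
        r = 100.0
        c1, c2 = (34.0, -118.0), (34.0 + 10_000 / 111_000.0, -118.0)  # 100x r apart
        pts = _blob(rng, c1, 5) + _blob(rng, c2, 5)
        clusters, assign = mean_shift_cluster(pts, radius_m=r)
        assert len(clusters) == 2
        assert sorted(c.visit_count for c in clusters) == [5, 5]
        for c, center in zip(sorted(clusters, key=lambda c: c.lat), sorted([c1, c2])):
            assert haversine_miles((c.lat, c.lon), center) * 1609.34 < r / 10

    def test_all_points_identical(self):
        pts = [StayPoint("P0", ts(1) + i * MIN, 34.0, -118.0) for i in range(4)]
        clusters, assign = mean_shift_cluster(pts, radius_m=100.0)
        assert len(clusters) == 1
        assert clusters[0].lat == pytest.approx(34.0)
        assert clusters[0].visit_count == 4

    def test_single_point(self):
        clusters, assign = mean_shift_cluster(
            [StayPoint("P0", ts(1), 34.0, -118.0)], radius_m=100.0
        )
        assert len(clusters) == 1 and clusters[0].visit_count == 1

    def test_order_and_translation_invariance(self):
        rng = np.random.default_rng(5)
        pts = _blob(rng, (40.0, -100.0), 6) + _blob(
            rng, (40.0 + 5000 / 111_000.0, -100.0), 4
        )
        base, _ = mean_shift_cluster(pts, radius_m=100.0)
        perm = [pts[i] for i in rng.permutation(len(pts))]
        shuffled, _ = mean_shift_cluster(perm, radius_m=100.0)
        assert sorted(c.visit_count for c in base) == sorted(c.visit_count for c in shuffled)
        dlat, dlon = 0.01, -0.02  # ~1-2 km shift
        moved = [StayPoint(p.participant_id, p.timestamp, p.lat + dlat, p.lon + dlon) for p in pts]
        translated, _ = mean_shift_cluster(moved, radius_m=100.0)
        for a, b in zip(base, translated):
            assert a.visit_count == b.visit_count
            assert abs(b.lat - a.lat - dlat) < 1e-5
            assert abs(b.lon - a.lon - dlon) < 1e-5

    def test_cluster_count_nonincreasing_in_radius(self):
        rng = np.random.default_rng(7)
        pts = []
        for k in range(4):
            pts += _blob(rng, (34.0 + k * 2000 / 111_000.0, -118.0), 4, spread_m=30.0)
        counts = []
        for r in (50.0, 150.0, 600.0, 3000.0, 10000.0):
            clusters, _ = mean_shift_cluster(pts, radius_m=r)
            counts.append(len(clusters))
        assert counts == sorted(counts, reverse=True)

    def test_matches_sklearn_on_well_separated_blobs(self):
        from sklearn.cluster import MeanShift

        rng = np.random.default_rng(11)
        centers = [(34.0, -118.0), (34.05, -118.0), (34.0, -118.06)]
        pts = []
        for c in centers:
            pts += _blob(rng, c, 6, spread_m=10.0)
        clusters, _ = mean_shift_cluster(pts, radius_m=150.0)
        X = np.array([[p.lat, p.lon] for p in pts])
        sk = MeanShift(bandwidth=150.0 / 111_000.0, bin_seeding=False).fit(X)
        assert len(clusters) == len(np.unique(sk.labels_)) == 3


class TestAssignHome:
    def test_argmax_visits(self):
        from phenorisk.mobility import PlaceCluster

        clusters = [
            PlaceCluster(0, 34.0, -118.0, visit_count=10, first_visit_ts=5),
            PlaceCluster(1, 35.0, -118.0, visit_count=3, first_visit_ts=1),
            PlaceCluster(2, 36.0, -118.0, visit_count=2, first_visit_ts=2),
        ]
        flagged = assign_home(clusters)
        assert [c.is_home for c in flagged] == [True, False, False]

    def test_tie_breaks_to_earlier_first_visit(self):
        from phenorisk.mobility import PlaceCluster

        clusters = [
            PlaceCluster(0, 34.0, -118.0, visit_count=5, first_visit_ts=100),
            PlaceCluster(1, 35.0, -118.0, visit_count=5, first_visit_ts=50),
        ]
        flagged = assign_home(clusters)
        assert [c.is_home for c in flagged] == [False, True]

    def test_single_cluster_is_home(self):
        from phenorisk.mobility import PlaceCluster

        (c,) = assign_home([PlaceCluster(0, 34.0, -118.0, 1, 0)])
        assert c.is_home


class TestMobilityFeatures:
    def _setup(self, distances_days):
        """Build stay points at given (miles-east-of-home, day) pairs."""
        home = (34.0, -118.0)
        pts = [StayPoint("P0", ts(d, 10), home[0], home[1]) for _, d in distances_days]
        away = []
        for i, (miles, d) in enumerate(distances_days):
            if miles > 0:
                lon = home[1] + miles / (69.0 * math.cos(math.radians(home[0])))
                away.append(StayPoint("P0", ts(d, 14), home[0], lon))
        pts = pts + away
        clusters, assign = mean_shift_cluster(pts, radius_m=100.0)
        clusters = assign_home(clusters)
        return pts, clusters, assign

    def test_all_home(self):
        pts = [StayPoint("P0", ts(d), 34.0, -118.0) for d in (1, 2, 3)]
        clusters, assign = mean_shift_cluster(pts, radius_m=100.0)
        clusters = assign_home(clusters)
        f = mobility_features(pts, clusters, assign)
        assert f["frac_over_50mi"] == 0.0
        assert f["frac_days_away"] == 0.0
        assert f["max_dist_home"] == pytest.approx(0.0, abs=1e-9)

    def test_quarter_of_staypoints_far(self):
        pts, clusters, assign = self._setup([(60, 1), (60, 2), (0, 3), (0, 4), (0, 5), (0, 6)])
        f = mobility_features(pts, clusters, assign)
        assert f["frac_over_50mi"] == pytest.approx(2 / 8)

    def test_three_day_trace_hand_tally(self):
        # day 1: home only; day 2: home + place 2 mi out; day 3: home + 60 mi out
        pts, clusters, assign = self._setup([(0, 1), (2, 2), (60, 3)])
        f = mobility_features(pts, clusters, assign)
        assert f["places_per_day"] == pytest.approx(5 / 3)
        assert f["frac_days_away"] == pytest.approx(2 / 3)
        assert f["frac_over_50mi"] == pytest.approx(1 / 5)
        assert f["n_unique_places"] == 3
        assert f["unique_places_per_day"] == pytest.approx((1 + 2 + 2) / 3)
        assert f["max_dist_home"] >= f["mean_dist_home"] >= 0

    def test_no_staypoints_missing_marked(self):
        f = mobility_features([], [], np.array([]))
        assert all(np.isnan(v) for v in f.values())


class TestPlantedPlaceRecovery:
    def test_k_places_recovered_with_home(self):
        """Planted-place parameter recovery across seeded replicates."""
        r = 100.0
        ok = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(1, 6))
            home = (float(rng.uniform(30, 45)), float(rng.uniform(-120, -75)))
            centers = [home] + [
                (home[0] + (i + 1) * 5000 / 111_000.0, home[1]) for i in range(k - 1)
            ]
            pts = []
            t = ts(1)
            # home gets strictly more visits than any other place
            for i, c in enumerate(centers):
                n = 8 if i == 0 else int(rng.integers(2, 6))
                for _ in range(n):
                    pts.append(
                        StayPoint(
                            "P0",
                            t,
                            c[0] + rng.normal(0, 5) / 111_000.0,
                            c[1] + rng.normal(0, 5) / 111_000.0,
                        )
                    )
                    t += MIN * 30
            clusters, _ = mean_shift_cluster(pts, radius_m=r)
            clusters = assign_home(clusters)
            home_cluster = next(c for c in clusters if c.is_home)
            if len(clusters) == k and haversine_miles(
                (home_cluster.lat, home_cluster.lon), home
            ) * 1609.34 < r:
                ok += 1
        assert ok / n_rep >= 0.95
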