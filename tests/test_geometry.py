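import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driftshift.geometry import (Centroid, assign_period, assign_periods, assign_scope,
                                 compare_ebird_gps, compute_shifts, gps_centroid,
                                 haversine_km, shift_distance, unit_vector_centroid,
                                 weighted_centroid, EARTH_RADIUS_KM)


class TestPeriods:
    @pytest.mark.parametrize("date,expected", [
        (dt.date(2021, 1, 1), "early"),
        (dt.date(2021, 2, 6), "early"),
        (dt.date(2021, 2, 7), "late"),
        (dt.date(2021, 2, 28), "late"),
    ])
    def test_boundaries(self, date, expected):
        assert assign_period(date) == expected

    def test_out_of_window_raises(self):
        with pytest.raises(ValueError):
            assign_period(dt.date(2021, 3, 3))
        with pytest.raises(ValueError):
            assign_period(dt.date(2020, 2, 29))  # leap day: excluded at ingest

    def test_calendar_enumeration(self):
        """Jan 1-Feb 28, 2021 splits into 37 early and 22 late days."""
        days = [dt.date(2021, 1, 1) + dt.timedelta(days=i) for i in range(59)]
        labels = [assign_period(d) for d in days]
        assert labels.count("early") == 37
        assert labels.count("late") == 22
        # vectorised path agrees
        vec = assign_periods(pd.Series(days))
        assert list(vec) == labels


class TestWeightedCentroid:
    def test_single_row(self):
        df = pd.DataFrame({"lat": [35.0], "lon": [-89.0], "count": [7]})
        c = weighted_centroid(df)
        assert (c.lat, c.lon, c.n) == (35.0, -89.0, 1)

    def test_closed_form_two_points(self):
        df = pd.DataFrame({"lat": [34.0, 36.0], "lon": [-90.0, -90.0], "count": [1, 3]})
        c = weighted_centroid(df)
        assert c.lat == pytest.approx(35.5, abs=1e-15)
        assert c.lon == -90.0

    def test_against_summation_oracle(self, rng):
        """50 seeded rows: matches an fsum-based independent oracle to 1e-12 rel."""
        df = pd.DataFrame({
            "lat": rng.uniform(25, 49, 50), "lon": rng.uniform(-124, -67, 50),
            "count": rng.integers(1, 500, 50),
        })
        c = weighted_centroid(df)
        w = df["count"].to_numpy(float)
        lat_oracle = math.fsum(w * df["lat"]) / math.fsum(w)
        lon_oracle = math.fsum(w * df["lon"]) / math.fsum(w)
        assert c.lat == pytest.approx(lat_oracle, rel=1e-12)
        assert c.lon == pytest.approx(lon_oracle, rel=1e-12)

    def test_zero_weight_and_empty_errors(self):
        df = pd.DataFrame({"lat": [35.0], "lon": [-89.0], "count": [0]})
        with pytest.raises(ValueError):
            weighted_centroid(df)
        with pytest.raises(ValueError):
            weighted_centroid(df.iloc[:0])

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariants(self, seed):
        """Bounding box containment, reorder invariance, weight-scale invariance."""
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 30))
        df = pd.DataFrame({"lat": r.uniform(25, 49, n), "lon": r.uniform(-124, -67, n),
                           "count": r.integers(1, 100, n)})
        c = weighted_centroid(df)
        assert df["lat"].min() <= c.lat <= df["lat"].max()
        assert df["lon"].min() <= c.lon <= df["lon"].max()
        perm = df.sample(frac=1, random_state=seed).reset_index(drop=True)
        c2 = weighted_centroid(perm)
        assert c2.lat == pytest.approx(c.lat, abs=1e-9)
        scaled = weighted_centroid(df.assign(count=df["count"] * 17))
        assert scaled.lat == pytest.approx(c.lat, abs=1e-9)
        assert scaled.lon == pytest.approx(c.lon, abs=1e-9)

    def test_unit_vector_agrees_at_small_extent(self, rng):
        df = pd.DataFrame({"lat": rng.uniform(34, 36, 20), "lon": rng.uniform(-91, -89, 20),
                           "count": rng.integers(1, 50, 20)})
        a = weighted_centroid(df)
        u = unit_vector_centroid(df)
        # small curvature difference is expected; both must agree to ~0.01 deg
        assert u.lat == pytest.approx(a.lat, abs=1e-2)
        assert u.lon == pytest.approx(a.lon, abs=1e-2)


class TestGpsCentroid:
    def test_all_fixes_identical(self):
        df = pd.DataFrame({"lat": [35.0] * 4, "lon": [-90.0] * 4, "region": ["AR"] * 4})
        for w in ("plain", "by_region"):
            c = gps_centroid(df, weighting=w)
            assert (c.lat, c.lon) == (35.0, -90.0)

    def test_region_frequency_weighting_closed_form(self):
        """90/10 fix split across regions at lat 34 and 36 -> pooled lat 34.2."""
        df = pd.DataFrame({
            "lat": [34.0] * 90 + [36.0] * 10, "lon": [-91.0] * 100,
            "region": ["AR"] * 90 + ["TN"] * 10,
        })
        c = gps_centroid(df, weighting="by_region")
        assert c.lat == pytest.approx(34.2, abs=1e-12)

    def test_plain_equals_by_region_identity(self, rng):
        """Frequency-weighting per-region centroids by fix counts is the plain mean."""
        df = pd.DataFrame({
            "lat": rng.uniform(33, 37, 200), "lon": rng.uniform(-92, -88, 200),
            "region": rng.choice(["AR", "TN"], 200, p=[0.3, 0.7]),
        })
        a = gps_centroid(df, weighting="plain")
        b = gps_centroid(df, weighting="by_region")
        assert b.lat == pytest.approx(a.lat, abs=1e-12)
        assert b.lon == pytest.approx(a.lon, abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gps_centroid(pd.DataFrame(columns=["lat", "lon", "region"]))


class TestShiftDistance:
    def test_identical_centroids_zero(self):
        c = Centroid(35.0, -90.0, 1.0, 1)
        assert shift_distance(c, c) == 0.0

    def test_one_degree_north(self):
        e = Centroid(34.0, -90.0, 1.0, 1)
        l = Centroid(35.0, -90.0, 1.0, 1)
        assert shift_distance(e, l) == pytest.approx(111.19, abs=0.01)
        assert shift_distance(l, e) == pytest.approx(-111.19, abs=0.01)

    def test_antisymmetry_random(self, rng):
        for _ in range(50):
            a = Centroid(*rng.uniform([25, -120], [49, -70]), 1.0, 1)
            b = Centroid(*rng.uniform([25, -120], [49, -70]), 1.0, 1)
            assert shift_distance(a, b) == pytest.approx(-shift_distance(b, a), rel=1e-12)

    def test_haversine_vs_law_of_cosines(self, rng):
        """1,000 random pairs: haversine matches the spherical law of cosines to 1e-6 rel."""
        p = rng.uniform([20, -130], [55, -60], size=(1000, 2))
        q = rng.uniform([20, -130], [55, -60], size=(1000, 2))
        d = haversine_km(p[:, 0], p[:, 1], q[:, 0], q[:, 1])
        la1, lo1, la2, lo2 = map(np.radians, (p[:, 0], p[:, 1], q[:, 0], q[:, 1]))
        cosang = np.sin(la1) * np.sin(la2) + np.cos(la1) * np.cos(la2) * np.cos(lo2 - lo1)
        oracle = EARTH_RADIUS_KM * np.arccos(np.clip(cosang, -1, 1))
        np.testing.assert_allclose(d, oracle, rtol=1e-6, atol=1e-9)


class TestCompare:
    @pytest.mark.parametrize("ebird,gps,expected", [(13, 19, 6), (22, -16, 38), (5, 5, 0)])
    def test_discrepancy(self, ebird, gps, expected):
        assert compare_ebird_gps(ebird, gps) == expected


class TestAssignScope:
    def test_point_in_one_polygon(self, flyways):
        pts = pd.DataFrame({"lat": [35.0], "lon": [-90.0]})
        out = assign_scope(pts, flyways)
        assert list(out["flyway"]) == ["Mississippi"]

    def test_lat_band_boundary(self, flyways):
        pts = pd.DataFrame({"lat": [37.6, 37.5, 32.5, 32.4], "lon": [-90.0] * 4})
        out = assign_scope(pts, flyways, lat_band=(32.5, 37.5))
        assert list(out["lat"]) == [37.5, 32.5]

    def test_outside_all_dropped(self, flyways):
        pts = pd.DataFrame({"lat": [35.0], "lon": [-60.0]})  # Atlantic ocean
        assert len(assign_scope(pts, flyways)) == 0

    def test_overlapping_polygons_error(self, flyways):
        from shapely.geometry import box
        bad = dict(flyways)
        bad["Rogue"] = box(-100.0, 30.0, -90.0, 40.0)
        with pytest.raises(ValueError, match="overlap"):
            assign_scope(pd.DataFrame({"lat": [35.0], "lon": [-90.0]}), bad)

    def test_against_ray_casting_oracle(self, flyways, rng):
        """1,000 random points: labels match a from-scratch point-in-polygon test."""
        pts = pd.DataFrame({"lat": rng.uniform(20, 55, 1000), "lon": rng.uniform(-130, -60, 1000)})
        out = assign_scope(pts, flyways)

        def ray_cast(x, y, ring):
            inside = False
            for (x1, y1), (x2, y2) in zip(ring, ring[1:]):
                if (y1 > y) != (y2 > y) and x < (x2 - x1) * (y - y1) / (y2 - y1) + x1:
                    inside = not inside
            return inside

        rings = {name: list(geom.exterior.coords) for name, geom in flyways.items()}
        for idx, row in pts.iterrows():
            hits = [n for n, ring in rings.items() if ray_cast(row["lon"], row["lat"], ring)]
            if idx in out.index:
                assert out.loc[idx, "flyway"] in hits or not hits  # boundary points: covers() vs strict
                if hits:
                    assert out.loc[idx, "flyway"] == hits[0]
            else:
                assert not hits


class TestComputeShifts:
    def test_recovers_direction_and_cells(self, flyways):
        rows = []
        cid = 0
        for period, lat in [("early", 33.0), ("late", 34.0)]:
            date = dt.date(2021, 1, 15) if period == "early" else dt.date(2021, 2, 15)
            for _ in range(5):
                cid += 1
                rows.append({"species": "MALL", "count": 10, "lat": lat, "lon": -90.0, "date": date})
        df = pd.DataFrame(rows)
        out = compute_shifts(df, flyways, scope="flyway")
        assert len(out) == 1
        rec = out.iloc[0]
        assert rec["scope"] == "Mississippi"
        assert rec["strategy"] == "generalist"
        assert rec["delta_km"] == pytest.approx(111.19, abs=0.01)
        assert rec["n_early"] == rec["n_late"] == 5

    def test_missing_period_cells_skipped(self, flyways):
        df = pd.DataFrame([{"species": "MALL", "count": 1, "lat": 35.0, "lon": -90.0,
                            "date": dt.date(2021, 1, 5)}])
        assert len(compute_shifts(df, flyways, scope="flyway")) == 0
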