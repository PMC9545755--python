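"""Periods, spatial subsetting, weighted centroids, and the signed shift statistic.

The distribution shift of a population between an "early" window (Jan 1-Feb 6)
and a "late" window (Feb 7-28) is summarised as the great-circle distance
between the abundance-weighted mean positions of the two windows, signed by
the north-south direction of the move (positive = northward).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .species import FLYWAYS, STRATEGY_BY_SPECIES

#: IUGG mean Earth radius, km. Fixed so distances are backend-independent.
EARTH_RADIUS_KM = 6371.0088

#: km per degree of latitude on the sphere of radius EARTH_RADIUS_KM.
KM_PER_DEG_LAT = EARTH_RADIUS_KM * np.pi / 180.0

#: Mallard eBird-vs-GPS comparison band (degrees N), inclusive on both ends.
MALLARD_LAT_BAND = (32.5, 37.5)


@dataclass(frozen=True)
class PeriodWindow:
    """Early/late split of the Jan 1-Feb 28 season.

    Early = Jan 1-Feb 6, late = Feb 7-28, both inclusive; the two windows are
    disjoint and cover the whole season.
    """

    early_end: tuple[int, int] = (2, 6)  # (month, day), inclusive
    late_end: tuple[int, int] = (2, 28)

    def assign(self, date: _dt.date) -> str:
        return assign_period(date, self)


DEFAULT_PERIODS = PeriodWindow()


def assign_period(date: _dt.date, window: PeriodWindow = DEFAULT_PERIODS) -> str:
    """Label a season date as ``"early"`` or ``"late"``.

    Raises ``ValueError`` for dates outside Jan 1 - Feb 28 (Feb 29 included:
    leap days are excluded at ingest and are not valid here).
    """
    md = (date.month, date.day)
    if md < (1, 1) or md > window.late_end:
        raise ValueError(f"date {date.isoformat()} outside the Jan 1-Feb 28 season window")
    return "early" if md <= window.early_end else "late"


def assign_periods(dates: pd.Series, window: PeriodWindow = DEFAULT_PERIODS) -> pd.Series:
    """Vectorised :func:`assign_period` over a Series of dates."""
    d = pd.to_datetime(dates)
    md = d.dt.month * 100 + d.dt.day
    early_key = window.early_end[0] * 100 + window.early_end[1]
    late_key = window.late_end[0] * 100 + window.late_end[1]
    if ((md < 101) | (md > late_key)).any():
        bad = d[(md < 101) | (md > late_key)].iloc[0]
        raise ValueError(f"date {bad.date().isoformat()} outside the Jan 1-Feb 28 season window")
    return pd.Series(np.where(md <= early_key, "early", "late"), index=dates.index, name="period")


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km on a sphere of radius ``EARTH_RADIUS_KM``."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    return d if d.ndim else float(d)


@dataclass(frozen=True)
class Centroid:
    """Abundance-weighted mean position of a set of records."""

    lat: float
    lon: float
    total_weight: float
    n: int

    def __post_init__(self):
        if not (-90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0):
            raise ValueError(f"centroid ({self.lat}, {self.lon}) out of geographic bounds")
        if self.total_weight <= 0:
            raise ValueError("centroid total_weight must be positive")


def weighted_centroid(rows: pd.DataFrame, weight: str | np.ndarray = "count",
                      lat: str = "lat", lon: str = "lon") -> Centroid:
    """Weighted arithmetic-mean centroid in geographic degrees.

    lat = sum(w_i lat_i)/sum(w_i), lon = sum(w_i lon_i)/sum(w_i).  Weights are
    typically abundances; they must be non-negative with positive total.
    """
    if len(rows) == 0:
        raise ValueError("cannot compute a centroid of zero rows")
    w = np.asarray(rows[weight] if isinstance(weight, str) else weight, dtype=float)
    if w.shape != (len(rows),):
        raise ValueError("weight vector length does not match rows")
    if (w < 0).any():
        raise ValueError("negative weights")
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total weight")
    la = np.asarray(rows[lat], dtype=float)
    lo = np.asarray(rows[lon], dtype=float)
    return Centroid(float((w * la).sum() / total), float((w * lo).sum() / total), float(total), int(len(rows)))


def unit_vector_centroid(rows: pd.DataFrame, weight: str | np.ndarray = "count",
                         lat: str = "lat", lon: str = "lon") -> Centroid:
    """Weighted mean of 3-D unit vectors, projected back to lat/lon.

    Longitude-wrap-safe alternative to :func:`weighted_centroid`; equivalent in
    the small-extent limit.  Off by default since conterminous-US data never
    straddle the antimeridian.
    """
    if len(rows) == 0:
        raise ValueError("cannot compute a centroid of zero rows")
    w = np.asarray(rows[weight] if isinstance(weight, str) else weight, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total weight")
    la = np.radians(np.asarray(rows[lat], dtype=float))
    lo = np.radians(np.asarray(rows[lon], dtype=float))
    x = (w * np.cos(la) * np.cos(lo)).sum()
    y = (w * np.cos(la) * np.sin(lo)).sum()
    z = (w * np.sin(la)).sum()
    norm = np.sqrt(x * x + y * y + z * z)
    if norm == 0:
        raise ValueError("degenerate (antipodally balanced) point set")
    return Centroid(float(np.degrees(np.arcsin(z / norm))),
                    float(np.degrees(np.arctan2(y, x))), float(total), int(len(rows)))


def gps_centroid(fixes: pd.DataFrame, weighting: str = "by_region",
                 lat: str = "lat", lon: str = "lon", region: str = "region") -> Centroid:
    """Centroid of GPS fixes.

    ``plain``: unweighted mean of all fixes.  ``by_region``: mean of per-region
    centroids weighted by each region's share of fixes — algebraically equal to
    ``plain`` (the frequency weights are the fix counts), kept as a separate
    code path because the two readings of "weighted by frequency of locations
    per state" are both exposed.
    """
    if len(fixes) == 0:
        raise ValueError("cannot compute a GPS centroid of zero fixes")
    if weighting == "plain":
        return weighted_centroid(fixes, np.ones(len(fixes)), lat=lat, lon=lon)
    if weighting != "by_region":
        raise ValueError(f"unknown weighting {weighting!r} (expected 'plain' or 'by_region')")
    parts = []
    for name, grp in fixes.groupby(region, sort=True):
        c = weighted_centroid(grp, np.ones(len(grp)), lat=lat, lon=lon)
        parts.append((len(grp), c))
    wsum = sum(n for n, _ in parts)
    la = sum(n * c.lat for n, c in parts) / wsum
    lo = sum(n * c.lon for n, c in parts) / wsum
    return Centroid(float(la), float(lo), float(wsum), int(len(fixes)))


def shift_distance(c_early: Centroid, c_late: Centroid) -> float:
    """Signed early->late displacement in km.

    Magnitude is the great-circle distance between the two centroids; the sign
    is the latitudinal direction of the move (+ north, - south, 0 if the
    latitudes coincide).
    """
    mag = haversine_km(c_early.lat, c_early.lon, c_late.lat, c_late.lon)
    sign = float(np.sign(c_late.lat - c_early.lat))
    return sign * mag if sign != 0.0 else 0.0


def compare_ebird_gps(ebird_delta_km: float, gps_delta_km: float) -> float:
    """Absolute discrepancy (km) between eBird- and GPS-derived signed shifts."""
    return abs(float(ebird_delta_km) - float(gps_delta_km))


def _check_non_overlapping(polygons: Mapping[str, BaseGeometry]) -> None:
    names = list(polygons)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = polygons[a].intersection(polygons[b])
            if inter.area > 1e-12:
                raise ValueError(f"flyway polygons {a!r} and {b!r} overlap (area {inter.area:g})")


def assign_scope(points: pd.DataFrame, flyway_polygons: Mapping[str, BaseGeometry],
                 lat_band: tuple[float, float] | None = None,
                 lat: str = "lat", lon: str = "lon") -> pd.DataFrame:
    """Label each point with its containing flyway; drop points outside all.

    Boundary points on a shared edge go to the first containing flyway in
    canonical order (Atlantic, Mississippi, Central, Pacific).  With
    ``lat_band=(lo, hi)``, only points with lo <= lat <= hi are kept.
    """
    _check_non_overlapping(flyway_polygons)
    out = points.copy()
    if lat_band is not None:
        lo, hi = lat_band
        out = out[(out[lat] >= lo) & (out[lat] <= hi)]
    geoms = shapely.points(np.column_stack([np.asarray(out[lon], float), np.asarray(out[lat], float)]))
    label = np.full(len(out), None, dtype=object)
    ordered = [f for f in FLYWAYS if f in flyway_polygons]
    ordered += [f for f in flyway_polygons if f not in ordered]
    for name in ordered:
        hit = shapely.covers(flyway_polygons[name], geoms)
        unassigned = pd.isna(label)
        label[hit & unassigned] = name
    out = out.assign(flyway=label)
    return out[~out["flyway"].isna()]


def compute_shifts(obs: pd.DataFrame, flyway_polygons: Mapping[str, BaseGeometry] | None = None,
                   scope: str = "flyway", lat_band: tuple[float, float] | None = None,
                   window: PeriodWindow = DEFAULT_PERIODS,
                   centroid_method: str = "arithmetic") -> pd.DataFrame:
    """Per (species, year, scope) early/late centroids and signed shift.

    ``obs`` must be filtered observation rows with resolved positive counts
    (columns species, count, lat, lon, date).  ``scope`` is ``"continental"``
    (no spatial subsetting beyond the optional ``lat_band``), ``"flyway"``
    (one record per flyway, requires polygons), or ``"lat-band"`` (continental
    restricted to ``lat_band``).

    Returns a DataFrame with one row per cell: species, year, scope,
    early/late centroid coordinates, delta_km, strategy, n_early, n_late.
    Cells missing either period are skipped.
    """
    cfun = weighted_centroid if centroid_method == "arithmetic" else unit_vector_centroid
    df = obs.copy()
    df["year"] = pd.to_datetime(df["date"]).dt.year
    df["period"] = assign_periods(df["date"], window)

    if scope == "flyway":
        if flyway_polygons is None:
            raise ValueError("flyway scope requires flyway polygons")
        df = assign_scope(df, flyway_polygons, lat_band=lat_band)
        scope_col = df["flyway"]
    elif scope in ("continental", "lat-band"):
        if scope == "lat-band":
            if lat_band is None:
                raise ValueError("lat-band scope requires lat_band")
            lo, hi = lat_band
            df = df[(df["lat"] >= lo) & (df["lat"] <= hi)]
        elif lat_band is not None:
            lo, hi = lat_band
            df = df[(df["lat"] >= lo) & (df["lat"] <= hi)]
        scope_col = pd.Series(scope, index=df.index)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    df = df.assign(_scope=scope_col)

    records = []
    for (species, year, sc), grp in df.groupby(["species", "year", "_scope"], sort=True):
        early = grp[grp["period"] == "early"]
        late = grp[grp["period"] == "late"]
        if len(early) == 0 or len(late) == 0:
            continue
        ce = cfun(early)
        cl = cfun(late)
        records.append({
            "species": species, "year": int(year), "scope": sc,
            "early_lat": ce.lat, "early_lon": ce.lon,
            "late_lat": cl.lat, "late_lon": cl.lon,
            "delta_km": shift_distance(ce, cl),
            "strategy": STRATEGY_BY_SPECIES[species],
            "n_early": ce.n, "n_late": cl.n,
        })
    return pd.DataFrame(records, columns=[
        "species", "year", "scope", "early_lat", "early_lon", "late_lat", "late_lon",
        "delta_km", "strategy", "n_early", "n_late"])
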