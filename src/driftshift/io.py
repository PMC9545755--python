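"""Readers and writers for every external format the pipeline touches.

Checklist tables travel as EBD-dialect TSV (both the raw eBird Basic Dataset
header names and this package's simplified lowercase schema are accepted),
GPS fixes as CSV, flyway boundaries as GeoJSON polygons in geographic
coordinates, and temperature-anomaly grids as flat netCDF (scipy backend)
with an explicit conterminous-US mask layer.

Coordinates are geographic degrees (WGS-84 assumed); no projection happens at
I/O time — the analysis modules own their own geodesy.  Presence-only "X"
counts are preserved as missing values in a nullable integer column paired
with a ``presence_only`` flag; resolving them is an analysis decision, not a
parsing one.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import shapely.geometry as sgeom
import xarray as xr
import yaml
from shapely.geometry.base import BaseGeometry

from .species import normalize_species

logger = logging.getLogger("driftshift")

#: Canonical observation-table columns, in order.
OBS_COLUMNS = ["checklist_id", "group_id", "species", "count", "presence_only",
               "lat", "lon", "date", "protocol", "travel_km", "duration_h",
               "n_observers", "complete"]

#: Raw EBD header -> canonical column.
EBD_HEADER_MAP = {
    "SAMPLING EVENT IDENTIFIER": "checklist_id",
    "GROUP IDENTIFIER": "group_id",
    "COMMON NAME": "species",
    "OBSERVATION COUNT": "count",
    "LATITUDE": "lat",
    "LONGITUDE": "lon",
    "OBSERVATION DATE": "date",
    "PROTOCOL TYPE": "protocol",
    "EFFORT DISTANCE KM": "travel_km",
    "DURATION MINUTES": "duration_minutes",
    "NUMBER OBSERVERS": "n_observers",
    "ALL SPECIES REPORTED": "complete",
}

_MANDATORY = ["checklist_id", "species", "count", "lat", "lon", "date",
              "protocol", "n_observers", "complete"]

_PROTOCOL_MAP = {"stationary": "stationary", "traveling": "traveling", "travelling": "traveling"}

#: Default season window: (month, day) bounds, inclusive.  Feb 29 never falls
#: inside, so leap days are dropped at ingest.
SEASON_WINDOW = ((1, 1), (2, 28))


def _to_bool(s: pd.Series) -> pd.Series:
    if s.dtype == bool:
        return s
    return s.astype(str).str.strip().str.lower().isin(["1", "true", "t", "yes"])


def read_ebd(path, season_window=SEASON_WINDOW) -> pd.DataFrame:
    """Read an EBD-dialect TSV into the canonical observation table.

    Accepts either the raw EBD header names or the simplified lowercase
    schema.  Rows outside the Jan 1 - Feb 28 season window are dropped at
    ingest; EBD ``DURATION MINUTES`` is converted to hours; rows with species
    outside the seven-species vocabulary are dropped with a logged count.

    Raises ``ValueError`` naming the first missing mandatory column.
    Unparseable rows (bad coordinates or dates) are skipped and logged.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rename = {}
    for col in raw.columns:
        if col in EBD_HEADER_MAP:
            rename[col] = EBD_HEADER_MAP[col]
        elif col.strip().lower() in OBS_COLUMNS + ["duration_minutes"]:
            rename[col] = col.strip().lower()
    raw = raw.rename(columns=rename)

    for col in _MANDATORY:
        if col not in raw.columns:
            raise ValueError(f"missing mandatory column: {col}")
    if "duration_h" not in raw.columns and "duration_minutes" not in raw.columns:
        raise ValueError("missing mandatory column: duration_h (or duration minutes)")

    df = pd.DataFrame(index=raw.index)
    df["checklist_id"] = raw["checklist_id"].str.strip()
    df["group_id"] = raw["group_id"].str.strip() if "group_id" in raw.columns else ""
    df["group_id"] = df["group_id"].replace("", pd.NA)

    species = raw["species"].map(lambda v: normalize_species(v) if v else None)
    n_unknown = int(species.isna().sum())
    if n_unknown:
        logger.info("read_ebd: dropping %d rows with species outside the 7-species vocabulary", n_unknown)
    df["species"] = species

    cnt = raw["count"].str.strip()
    df["presence_only"] = cnt.str.upper().eq("X")
    df["count"] = pd.to_numeric(cnt.where(~df["presence_only"]), errors="coerce").astype("Int64")

    df["lat"] = pd.to_numeric(raw["lat"], errors="coerce")
    df["lon"] = pd.to_numeric(raw["lon"], errors="coerce")
    df["date"] = pd.to_datetime(raw["date"], errors="coerce", format="mixed")

    proto = raw["protocol"].str.strip().str.lower()
    # EBD protocol names look like "eBird - Stationary Count" / "Traveling".
    df["protocol"] = "other"
    for key, canon in _PROTOCOL_MAP.items():
        df.loc[proto.str.contains(key, regex=False), "protocol"] = canon

    df["travel_km"] = pd.to_numeric(raw.get("travel_km", pd.Series("", index=raw.index)), errors="coerce")
    if "duration_h" in raw.columns:
        df["duration_h"] = pd.to_numeric(raw["duration_h"], errors="coerce")
    else:
        df["duration_h"] = pd.to_numeric(raw["duration_minutes"], errors="coerce") / 60.0
    df["n_observers"] = pd.to_numeric(raw["n_observers"], errors="coerce")
    df["complete"] = _to_bool(raw["complete"])

    df = df[df["species"].notna()]
    parse_ok = (df["lat"].between(-90, 90) & df["lon"].between(-180, 180)
                & df["date"].notna() & df["n_observers"].notna()
                & (df["count"].notna() | df["presence_only"]))
    n_bad = int((~parse_ok).sum())
    if n_bad:
        logger.info("read_ebd: skipping %d unparseable rows", n_bad)
    df = df[parse_ok]

    md = df["date"].dt.month * 100 + df["date"].dt.day
    lo = season_window[0][0] * 100 + season_window[0][1]
    hi = season_window[1][0] * 100 + season_window[1][1]
    df = df[(md >= lo) & (md <= hi)]

    df = df.astype({"n_observers": int})
    df["date"] = df["date"].dt.date
    return df[OBS_COLUMNS].reset_index(drop=True)


def write_ebd(rows: pd.DataFrame, path) -> None:
    """Write the canonical observation table as simplified-schema TSV.

    Presence-only records are serialised with count ``X``; the round-trip
    through :func:`read_ebd` is lossless on the canonical columns.
    """
    out = rows.copy()
    cnt = out["count"].astype(object)
    cnt[out["presence_only"].astype(bool)] = "X"
    out["count"] = cnt
    out = out.drop(columns=["presence_only"])
    out["complete"] = out["complete"].astype(bool)
    out.to_csv(path, sep="\t", index=False)


def read_gps(path) -> pd.DataFrame:
    """Read a GPS fix CSV (bird_id, timestamp, lat, lon, region).

    Timestamps are parsed as UTC instants; per-bird timestamps must be
    strictly increasing and regions non-empty.
    """
    df = pd.read_csv(path, dtype={"bird_id": str, "region": str}, float_precision="round_trip")
    for col in ["bird_id", "timestamp", "lat", "lon", "region"]:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    if df["region"].isna().any() or (df["region"].str.strip() == "").any():
        raise ValueError("GPS fixes with empty region label")
    for bird, grp in df.groupby("bird_id"):
        if not grp["timestamp"].is_monotonic_increasing or grp["timestamp"].duplicated().any():
            raise ValueError(f"timestamps not strictly increasing for bird {bird}")
    return df[["bird_id", "timestamp", "lat", "lon", "region"]]


def write_gps(fixes: pd.DataFrame, path) -> None:
    out = fixes.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_flyways(path) -> dict[str, BaseGeometry]:
    """Read flyway polygons from GeoJSON (geographic lat-lon CRS only).

    Each feature must carry a ``flyway`` name property and a polygonal
    geometry; returns an insertion-ordered name -> shapely geometry map.
    """
    with open(path) as fh:
        gj = json.load(fh)
    crs = gj.get("crs")
    if crs is not None:
        name = str(crs.get("properties", {}).get("name", ""))
        if not ("CRS84" in name or "4326" in name):
            raise ValueError(f"flyway GeoJSON must be in geographic lat-lon coordinates, got CRS {name!r}")
    out: dict[str, BaseGeometry] = {}
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        if "flyway" not in props:
            raise ValueError("flyway feature lacks a 'flyway' name property")
        geom = sgeom.shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(f"flyway {props['flyway']!r} geometry is {geom.geom_type}, not polygonal")
        if not geom.is_valid:
            raise ValueError(f"flyway {props['flyway']!r} geometry is invalid")
        out[str(props["flyway"])] = geom
    if not out:
        raise ValueError("no flyway features found")
    return out


def write_flyways(polygons: Mapping[str, BaseGeometry], path) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"flyway": name}, "geometry": sgeom.mapping(geom)}
            for name, geom in polygons.items()
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


@dataclass
class AnomalyGrid:
    """A gridded February temperature-anomaly field with a land mask.

    ``values`` are anomalies in degrees C; ``mask`` flags conterminous-US
    cells; ``cell_area`` (km^2, optional) enables area-weighted fractions.
    """

    values: np.ndarray
    mask: np.ndarray
    cell_area: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not self.mask.any():
            raise ValueError("anomaly grid mask has no true cells")
        if self.cell_area is not None:
            self.cell_area = np.asarray(self.cell_area, dtype=float)
            if self.cell_area.shape != self.values.shape:
                raise ValueError("cell_area shape differs from values")


def read_anomaly(path) -> AnomalyGrid:
    """Read an anomaly grid from flat netCDF (variables anomaly, mask[, cell_area])."""
    with xr.open_dataset(path, engine="scipy") as ds:
        values = ds["anomaly"].values.astype(float)
        mask = ds["mask"].values.astype(bool)
        area = ds["cell_area"].values.astype(float) if "cell_area" in ds else None
    return AnomalyGrid(values=values, mask=mask, cell_area=area)


def write_anomaly(grid: AnomalyGrid, path) -> None:
    data = {"anomaly": (("y", "x"), grid.values),
            "mask": (("y", "x"), grid.mask.astype("int8"))}
    if grid.cell_area is not None:
        data["cell_area"] = (("y", "x"), grid.cell_area)
    xr.Dataset(data, attrs={"units": "degC anomaly"}).to_netcdf(path, engine="scipy")


def read_run_config(path) -> dict:
    """Load a YAML run configuration as a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a YAML mapping")
    return cfg
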