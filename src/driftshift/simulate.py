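"""Synthetic checklists, GPS fixes, flyway polygons, and anomaly grids.

Every downstream stage is testable without external data because each
generator has configurable ground truth: observation positions scatter
isotropically (Gaussian, in km) around per-cell true centroids, counts are
negative-binomial with a configurable presence-only ("X") rate, filtering-rule
violations are injected at known rates, GPS fix streams reproduce the
deployment imbalance of the telemetry study (84 vs 210 marked birds in the
two states), and anomaly grids contain an exact count of cold cells.

All randomness flows from ``SimConfig.seed`` through a fixed spawn key per
table, so the same seed and config give byte-identical outputs regardless of
generator call order.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from .geometry import KM_PER_DEG_LAT, DEFAULT_PERIODS, PeriodWindow
from .io import OBS_COLUMNS, AnomalyGrid, write_anomaly, write_ebd, write_flyways, write_gps
from .species import SPECIES_CODES, STRATEGIES, STRATEGY_BY_SPECIES

_TABLE_KEYS = {"checklists": 0, "gps": 1, "anomaly": 2, "shifts": 3}

#: Violation-rate keys understood by the checklist generator, mapping to the
#: filter rule each one trips.
VIOLATION_KEYS = ("complete", "travel", "duplicate", "observers", "group", "duration")

#: Default severe (event) years within the study span.
DEFAULT_ECE_YEARS = (2015, 2019, 2021)


def _rng(seed: int, table: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_TABLE_KEYS[table],)))


@dataclass(frozen=True)
class Eq1Effects:
    """True fixed effects and variance components of the shift model, in km.

    Defaults are the continental-scale magnitudes of the study system: a
    generalist non-event northward shift of ~143 km, grubbers shifting ~43 km
    farther and wetland obligates ~86 km less, an event main effect of
    -85 km, and strategy-specific event interactions making grubbers the most
    event-sensitive guild.
    """

    beta0: float = 143.0
    strategy: dict[str, float] = field(default_factory=lambda: {"grubbing": 43.0, "wetland_obligate": -86.0})
    ece: float = -85.0
    interaction: dict[str, float] = field(default_factory=lambda: {"grubbing": -115.0, "wetland_obligate": 11.0})
    sigma_year: float = 25.0
    sigma_eps: float = 120.0

    def __post_init__(self):
        if self.sigma_year < 0 or self.sigma_eps < 0:
            raise ValueError("sigma_year and sigma_eps must be >= 0")

    def cell_mean(self, strategy: str, ece: bool) -> float:
        """Population mean shift (km) of one strategy x event cell."""
        mu = self.beta0 + self.strategy.get(strategy, 0.0)
        if ece:
            mu += self.ece + self.interaction.get(strategy, 0.0)
        return mu

    def as_truth(self) -> dict[str, float]:
        return {
            "beta0": self.beta0,
            "beta_grubbing": self.strategy.get("grubbing", 0.0),
            "beta_wetland_obligate": self.strategy.get("wetland_obligate", 0.0),
            "beta_ece": self.ece,
            "beta_grubbing_x_ece": self.interaction.get("grubbing", 0.0),
            "beta_wetland_obligate_x_ece": self.interaction.get("wetland_obligate", 0.0),
            "sigma_year": self.sigma_year,
            "sigma_eps": self.sigma_eps,
        }


@dataclass(frozen=True)
class CountModel:
    """Negative-binomial abundance model (mean + dispersion parameterisation)."""

    mean: float = 20.0
    dispersion: float = 1.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        k, mu = self.dispersion, self.mean
        return rng.negative_binomial(k, k / (k + mu), size=size)


@dataclass(frozen=True)
class GpsConfig:
    """GPS fix-stream settings.

    Defaults mirror the 2021 telemetry deployment: 84 birds in Arkansas and
    210 in Tennessee, recording on a fixed cadence through Jan 1 - Feb 28.
    """

    year: int = 2021
    birds_per_region: dict[str, int] = field(default_factory=lambda: {"AR": 84, "TN": 210})
    region_centers: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"AR": (34.8, -91.2), "TN": (35.8, -88.9)})
    fix_interval_h: float = 6.0
    bird_scatter_km: float = 30.0
    fix_dispersion_km: float = 5.0
    late_shift_km: float = 0.0  # northward displacement of activity in the late window


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth configuration shared by all generators."""

    seed: int = 0
    years: tuple[int, ...] = tuple(range(2008, 2022))
    species: tuple[str, ...] = SPECIES_CODES
    true_centroids: dict[tuple[str, int, str, str], tuple[float, float]] = field(default_factory=dict)
    observers_per_cell: int = 30
    dispersion_km: float = 150.0
    count_model: CountModel = field(default_factory=CountModel)
    presence_only_rate: float = 0.05
    violation_rates: dict[str, float] = field(default_factory=dict)
    eq1_effects: Eq1Effects = field(default_factory=Eq1Effects)
    gps: GpsConfig = field(default_factory=GpsConfig)
    records_per_cell: int = 100

    def __post_init__(self):
        if not (0.0 <= self.presence_only_rate <= 1.0):
            raise ValueError("presence_only_rate must lie in [0, 1]")
        for name, p in self.violation_rates.items():
            if name not in VIOLATION_KEYS:
                raise ValueError(f"unknown violation rate {name!r}; known: {VIOLATION_KEYS}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"violation rate {name!r}={p} outside [0, 1]")
        if self.dispersion_km <= 0:
            raise ValueError("dispersion_km must be positive")
        if self.observers_per_cell < 1 or self.records_per_cell < 1:
            raise ValueError("per-cell sizes must be positive")


#: Simplified longitudinal flyway bands over the conterminous-US bounding box.
_FLYWAY_BOUNDS = {
    "Atlantic": (-82.0, -66.0),
    "Mississippi": (-95.0, -82.0),
    "Central": (-107.0, -95.0),
    "Pacific": (-125.0, -107.0),
}


def gen_flyways() -> dict:
    """Four simplified non-overlapping flyway polygons (lat 24-50 N bands)."""
    return {name: box(w, 24.0, e, 50.0) for name, (w, e) in _FLYWAY_BOUNDS.items()}


def make_true_centroids(cfg: SimConfig, ece_years=DEFAULT_ECE_YEARS,
                        base_lat: float = 33.5) -> dict:
    """Per-cell true centroids implied by the configured shift-model effects.

    The early centroid of every (species, year, flyway) cell sits at
    ``base_lat`` on the flyway's central meridian; the late centroid lies the
    cell-mean shift north of it (negative means south).  This ties the
    checklist generator's ground truth to the same effect sizes the shift
    model is meant to recover.
    """
    out = {}
    for species in cfg.species:
        strategy = STRATEGY_BY_SPECIES[species]
        for year in cfg.years:
            shift_km = cfg.eq1_effects.cell_mean(strategy, year in tuple(ece_years))
            for flyway, (w, e) in _FLYWAY_BOUNDS.items():
                lon = (w + e) / 2.0
                out[(species, year, "early", flyway)] = (base_lat, lon)
                out[(species, year, "late", flyway)] = (base_lat + shift_km / KM_PER_DEG_LAT, lon)
    return out


def _period_dates(year: int, period: str, window: PeriodWindow = DEFAULT_PERIODS) -> list[_dt.date]:
    start = _dt.date(year, 1, 1) if period == "early" else _dt.date(year, *window.early_end) + _dt.timedelta(days=1)
    end = _dt.date(year, *window.early_end) if period == "early" else _dt.date(year, *window.late_end)
    return [start + _dt.timedelta(days=i) for i in range((end - start).days + 1)]


def gen_checklists(cfg: SimConfig) -> pd.DataFrame:
    """Generate one observation row per simulated checklist.

    Clean rows scatter isotropically (sd ``dispersion_km``) around their
    cell's true centroid; a known fraction violate each filtering rule per
    ``violation_rates`` (independent Bernoulli marks per rule, so a row may
    violate several).  A trailing ``violations`` audit column names the rules
    each row was made to violate.

    Raises ``ValueError`` naming any requested (species, year, period,
    flyway) cell that lacks a true centroid.
    """
    centroids = cfg.true_centroids or make_true_centroids(cfg)
    flyways = sorted({k[3] for k in centroids})
    if not flyways:
        raise ValueError("true_centroids is empty")
    rng = _rng(cfg.seed, "checklists")

    cells = []
    for species in cfg.species:
        for year in cfg.years:
            for period in ("early", "late"):
                for flyway in flyways:
                    key = (species, year, period, flyway)
                    if key not in centroids:
                        raise ValueError(f"no true centroid configured for cell {key}")
                    cells.append(key)

    rows = []
    counter = 0
    for key in cells:
        species, year, period, flyway = key
        clat, clon = centroids[key]
        dates = _period_dates(year, period)
        n = cfg.observers_per_cell
        dkm = rng.normal(0.0, cfg.dispersion_km, size=(n, 2))
        lats = clat + dkm[:, 0] / KM_PER_DEG_LAT
        lons = clon + dkm[:, 1] / (KM_PER_DEG_LAT * np.cos(np.radians(clat)))
        counts = cfg.count_model.sample(rng, n)
        xmask = rng.uniform(size=n) < cfg.presence_only_rate
        traveling = rng.uniform(size=n) < 0.5
        travel = np.where(traveling, rng.uniform(0.0, 4.9, size=n), np.nan)
        dur = rng.uniform(0.25, 5.0, size=n)
        nobs = rng.integers(1, 5, size=n)
        didx = rng.integers(0, len(dates), size=n)
        for i in range(n):
            counter += 1
            rows.append({
                "checklist_id": f"S{counter:08d}", "group_id": pd.NA,
                "species": species,
                "count": pd.NA if xmask[i] else int(counts[i]),
                "presence_only": bool(xmask[i]),
                "lat": float(lats[i]), "lon": float(lons[i]), "date": dates[didx[i]],
                "protocol": "traveling" if traveling[i] else "stationary",
                "travel_km": float(travel[i]) if traveling[i] else np.nan,
                "duration_h": float(dur[i]), "n_observers": int(nobs[i]),
                "complete": True, "violations": "",
            })
    df = pd.DataFrame(rows)

    marks = {name: rng.uniform(size=len(df)) < p for name, p in sorted(cfg.violation_rates.items())}
    any_mark = np.zeros(len(df), dtype=bool)
    for m in marks.values():
        any_mark |= m
    clean_idx = np.flatnonzero(~any_mark)

    viol = df["violations"].to_numpy(dtype=object)
    group_counter = 0
    for name in VIOLATION_KEYS:
        if name not in marks:
            continue
        for i in np.flatnonzero(marks[name]):
            if name == "complete":
                df.iat[i, df.columns.get_loc("complete")] = False
            elif name == "travel":
                df.iat[i, df.columns.get_loc("protocol")] = "traveling"
                df.iat[i, df.columns.get_loc("travel_km")] = float(rng.uniform(5.0, 20.0))
            elif name == "duration":
                df.iat[i, df.columns.get_loc("duration_h")] = float(5.0 + rng.uniform(0.1, 7.0))
            elif name == "observers":
                df.iat[i, df.columns.get_loc("n_observers")] = int(rng.integers(11, 21))
            elif name in ("duplicate", "group"):
                # needs a clean partner with a smaller checklist id so the
                # deterministic tie-break removes the violator, not the partner
                partners = clean_idx[clean_idx < i]
                if len(partners) == 0:
                    continue
                j = int(partners[rng.integers(0, len(partners))])
                if name == "duplicate":
                    for col in ("lat", "lon", "date", "species"):
                        df.iat[i, df.columns.get_loc(col)] = df.iat[j, df.columns.get_loc(col)]
                else:
                    group_counter += 1
                    gid = f"G{group_counter:06d}"
                    df.iat[i, df.columns.get_loc("group_id")] = gid
                    df.iat[j, df.columns.get_loc("group_id")] = gid
            viol[i] = (viol[i] + "," + name).lstrip(",")
    df["violations"] = viol
    df["count"] = df["count"].astype("Int64")
    return df


def gen_gps_fixes(cfg: SimConfig) -> pd.DataFrame:
    """Generate per-bird GPS fix streams on a fixed cadence over the season.

    Each bird's activity centre scatters (sd ``bird_scatter_km``) around its
    deployment region's centre; fixes scatter (sd ``fix_dispersion_km``)
    around the activity centre, displaced ``late_shift_km`` north in the late
    window.  Zero birds requested gives an empty table with a warning.
    """
    g = cfg.gps
    rng = _rng(cfg.seed, "gps")
    if sum(g.birds_per_region.values()) == 0:
        warnings.warn("gen_gps_fixes: zero birds requested; returning empty table")
        return pd.DataFrame(columns=["bird_id", "timestamp", "lat", "lon", "region"])

    start = _dt.datetime(g.year, 1, 1, tzinfo=_dt.timezone.utc)
    end = _dt.datetime(g.year, 3, 1, tzinfo=_dt.timezone.utc)
    step = _dt.timedelta(hours=g.fix_interval_h)
    stamps = []
    t = start
    while t < end:
        stamps.append(t)
        t += step
    late_start = _dt.datetime(g.year, 2, 7, tzinfo=_dt.timezone.utc)
    late = np.array([t >= late_start for t in stamps])

    rows = []
    for region in sorted(g.birds_per_region):
        clat, clon = g.region_centers[region]
        for b in range(g.birds_per_region[region]):
            bid = f"{region}{b + 1:04d}"
            ckm = rng.normal(0.0, g.bird_scatter_km, size=2)
            blat = clat + ckm[0] / KM_PER_DEG_LAT
            blon = clon + ckm[1] / (KM_PER_DEG_LAT * np.cos(np.radians(clat)))
            fkm = rng.normal(0.0, g.fix_dispersion_km, size=(len(stamps), 2))
            lats = blat + fkm[:, 0] / KM_PER_DEG_LAT + late * g.late_shift_km / KM_PER_DEG_LAT
            lons = blon + fkm[:, 1] / (KM_PER_DEG_LAT * np.cos(np.radians(blat)))
            for t, la, lo in zip(stamps, lats, lons):
                rows.append({"bird_id": bid, "timestamp": t, "lat": float(la),
                             "lon": float(lo), "region": region})
    return pd.DataFrame(rows)


def expected_fixes_per_bird(cfg: SimConfig) -> int:
    """Fix count per bird implied by the cadence (Jan 1 up to Mar 1, exclusive)."""
    total_h = (_dt.datetime(cfg.gps.year, 3, 1) - _dt.datetime(cfg.gps.year, 1, 1)).total_seconds() / 3600.0
    return int(np.ceil(total_h / cfg.gps.fix_interval_h))


def gen_anomaly_grid(fraction_below: float, threshold: float = -4.0,
                     shape: tuple[int, int] = (40, 80), seed: int = 0,
                     with_area: bool = False) -> AnomalyGrid:
    """A masked anomaly grid with an exact count of cold cells.

    Exactly ``round(fraction_below * n_masked_cells)`` masked cells get
    anomalies at or below ``threshold``; every other masked cell is strictly
    warmer.  The mask is an elliptical pseudo-continent inscribed in the grid.
    """
    if not (0.0 <= fraction_below <= 1.0):
        raise ValueError("fraction_below must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_TABLE_KEYS["anomaly"],)))
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    mask = (((yy - (ny - 1) / 2) / (0.45 * ny)) ** 2 + ((xx - (nx - 1) / 2) / (0.45 * nx)) ** 2) <= 1.0
    n_masked = int(mask.sum())
    if n_masked == 0:
        raise ValueError("empty mask")
    k = int(np.rint(fraction_below * n_masked))

    values = rng.normal(0.0, 2.0, size=shape)
    midx = np.flatnonzero(mask.ravel())
    cold = rng.choice(midx, size=k, replace=False)
    warm = np.setdiff1d(midx, cold)
    flat = values.ravel()
    flat[cold] = threshold - np.abs(rng.normal(0.0, 3.0, size=k))
    flat[warm] = threshold + 0.5 + np.abs(rng.normal(0.0, 3.0, size=len(warm)))
    area = None
    if with_area:
        area = np.full(shape, 1.0) + 0.2 * (yy / max(ny - 1, 1))  # mild latitudinal gradient
    return AnomalyGrid(values=flat.reshape(shape), mask=mask, cell_area=area)


def gen_shift_dataset(cfg: SimConfig, ece_years=None, n_per_cell: int | None = None,
                      scope: str = "continental") -> tuple[pd.DataFrame, dict]:
    """Draw shift records directly from the configured shift-model effects.

    delta = cell mean + year random intercept + Gaussian noise.  Species are
    assigned round-robin within each strategy guild.  Returns the record
    table and a truth dict (fixed effects, scales, realised year intercepts,
    event years) for recovery tests.
    """
    eff = cfg.eq1_effects
    years = list(cfg.years)
    if ece_years is None:
        ece_years = DEFAULT_ECE_YEARS
    ece_years = sorted(set(int(y) for y in ece_years) & set(years))
    n = n_per_cell or cfg.records_per_cell
    rng = _rng(cfg.seed, "shifts")

    alpha = {y: rng.normal(0.0, eff.sigma_year) if eff.sigma_year > 0 else 0.0 for y in years}
    by_strategy = {s: [sp for sp in cfg.species if STRATEGY_BY_SPECIES[sp] == s] for s in STRATEGIES}
    rows = []
    for year in years:
        is_ece = year in ece_years
        for strategy in STRATEGIES:
            mu = eff.cell_mean(strategy, is_ece) + alpha[year]
            noise = rng.normal(0.0, eff.sigma_eps, size=n) if eff.sigma_eps > 0 else np.zeros(n)
            pool = by_strategy[strategy] or [f"<{strategy}>"]
            for i in range(n):
                rows.append({"species": pool[i % len(pool)], "year": year, "scope": scope,
                             "delta_km": float(mu + noise[i]), "strategy": strategy,
                             "ece": is_ece})
    truth = eff.as_truth()
    truth["alpha"] = dict(alpha)
    truth["ece_years"] = list(ece_years)
    return pd.DataFrame(rows), truth


def write_bundle(cfg: SimConfig, outdir, severe_fraction: float = 0.25,
                 mild_fraction: float = 0.05, ece_years=DEFAULT_ECE_YEARS) -> dict[str, str]:
    """Write the full synthetic input bundle for a pipeline run.

    Produces ``ebd.tsv``, ``gps.csv``, ``flyways.geojson`` and one
    ``anomaly_<year>.nc`` per study year (severe years get cold coverage
    ``severe_fraction``, others ``mild_fraction``).  Returns name -> path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    ebd = outdir / "ebd.tsv"
    write_ebd(gen_checklists(cfg).drop(columns=["violations"]), ebd)
    paths["ebd"] = str(ebd)

    gps = outdir / "gps.csv"
    write_gps(gen_gps_fixes(cfg), gps)
    paths["gps"] = str(gps)

    fly = outdir / "flyways.geojson"
    write_flyways(gen_flyways(), fly)
    paths["flyways"] = str(fly)

    for year in cfg.years:
        frac = severe_fraction if year in tuple(ece_years) else mild_fraction
        p = outdir / f"anomaly_{year}.nc"
        write_anomaly(gen_anomaly_grid(frac, seed=cfg.seed + year), p)
        paths[f"anomaly_{year}"] = str(p)
    return paths
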