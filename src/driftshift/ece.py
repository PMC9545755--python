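"""Severe-February classification and construction of the two analysis designs.

A February is *severe* when temperature anomalies of -4 degC or colder cover
strictly more than 15% of the conterminous United States.  Two designs feed
the hierarchical model:

* ``ece2021`` — the February 2021 polar-vortex analysis: years 2015 and 2019
  (also abnormally cold) are removed so the contrast isolates the 2021 event,
  and the event indicator is true only for 2021.  Fit continentally and per
  flyway.
* ``severe_feb`` — the severe-February analysis: all years stay in, the
  indicator follows the severe-February classification (2015, 2019, 2021),
  and only the continental scope is fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import AnomalyGrid

#: Years excluded from the 2021-event analysis because of their own cold anomalies.
ECE_EXCLUDED_YEARS = (2015, 2019)
ECE_YEAR = 2021

SEVERE_THRESHOLD_C = -4.0
SEVERE_FRACTION = 0.15


@dataclass(frozen=True)
class YearLabel:
    """Per-year flags driving the two analyses."""

    year: int
    severe_feb: bool
    in_ece_design: bool
    ece_2021: bool

    def __post_init__(self):
        if self.ece_2021 and not self.severe_feb:
            raise ValueError(f"year {self.year}: ece_2021 implies severe_feb")
        if self.year in ECE_EXCLUDED_YEARS and self.in_ece_design:
            raise ValueError(f"year {self.year} must be excluded from the ECE design")


def make_year_labels(severe_by_year: Mapping[int, bool]) -> dict[int, YearLabel]:
    """Build consistent labels from a year -> severe-February map."""
    out = {}
    for year, severe in severe_by_year.items():
        year = int(year)
        out[year] = YearLabel(
            year=year,
            severe_feb=bool(severe),
            in_ece_design=year not in ECE_EXCLUDED_YEARS,
            ece_2021=(year == ECE_YEAR and bool(severe)),
        )
    return out


def classify_severe_february(grid: AnomalyGrid, threshold: float = SEVERE_THRESHOLD_C,
                             fraction: float = SEVERE_FRACTION) -> bool:
    """True iff anomalies <= ``threshold`` cover > ``fraction`` of the masked area.

    Cell-count based by default; area-weighted when the grid carries cell
    areas.  Both inequalities are strict/inclusive exactly as stated: cells at
    the threshold count as cold, a coverage of exactly ``fraction`` does not
    qualify.
    """
    if not grid.mask.any():
        raise ValueError("anomaly grid mask has no true cells")
    cold = (grid.values <= threshold) & grid.mask
    if grid.cell_area is not None:
        frac = grid.cell_area[cold].sum() / grid.cell_area[grid.mask].sum()
    else:
        frac = cold.sum() / grid.mask.sum()
    return bool(frac > fraction)


def build_design(shifts: pd.DataFrame, labels: Mapping[int, YearLabel],
                 analysis: str) -> pd.DataFrame:
    """Subset and label shift records for one of the two analyses.

    Pure subsetting/labeling: ``delta_km`` values are never altered.  Raises
    ``KeyError`` naming any shift year without a label.
    """
    if analysis not in ("ece2021", "severe_feb"):
        raise ValueError(f"analysis must be 'ece2021' or 'severe_feb', got {analysis!r}")
    missing = sorted(set(shifts["year"].astype(int)) - set(labels))
    if missing:
        raise KeyError(f"no year label for year(s): {missing}")
    df = shifts.copy()
    years = df["year"].astype(int)
    if analysis == "ece2021":
        keep = years.map(lambda y: labels[y].in_ece_design)
        df = df[keep]
        df["ece"] = df["year"].astype(int).map(lambda y: labels[y].ece_2021)
    else:
        df["ece"] = years.map(lambda y: labels[y].severe_feb)
        if "scope" in df.columns:
            df = df[df["scope"] == "continental"]
    return df.reset_index(drop=True)
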