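"""Semi-structured checklist filtering with a per-rule attrition audit.

Citizen-science checklists carry effort metadata precisely so that
effort-based detection biases can be controlled by filtering.  The protocol
applied here, in order:

1. keep only *complete* checklists (every detected species reported);
2. keep stationary protocols, or traveling protocols with <5 km travelled;
3. keep one record per unique (latitude, longitude, date) combination so
   heavily-surveyed sites are not over-represented;
4. drop checklists with >10 observers;
5. drop duplicate (group-shared) checklists — at most one per group;
6. limit checklists to <=5 h duration.

Rules 3 and 5 need a deterministic tie-break: the record with the
lexicographically smallest checklist id is kept, which makes the surviving
set independent of input order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

RULE_NAMES = ("complete", "protocol", "unique_location_date", "observers", "group_duplicate", "duration")


@dataclass
class FilterReport:
    """Ordered per-rule attrition counts for one filtering pass."""

    n_input: int
    removed: dict[str, int]
    n_output: int

    def __post_init__(self):
        if self.n_input - sum(self.removed.values()) != self.n_output:
            raise ValueError("inconsistent report: input - removed != output")
        if self.n_input < 0 or self.n_output < 0 or any(v < 0 for v in self.removed.values()):
            raise ValueError("negative counts in filter report")

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "removed": dict(self.removed), "n_output": self.n_output}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


class ChecklistFilter(TransformerMixin, BaseEstimator):
    """Stateless transformer applying the six-rule effort filter in order.

    Parameters
    ----------
    dedupe : {"per_species", "per_checklist"}
        Key for the unique-location-date rule.  ``per_species`` keeps one row
        per (lat, lon, date, species); ``per_checklist`` keeps every row of
        the single surviving checklist per (lat, lon, date).
    drop_missing_duration : bool
        A checklist whose duration is unrecorded cannot be confirmed <=5 h;
        by default such rows are removed by the duration rule.

    The last ``transform`` call's audit is exposed as ``report_``.
    Coordinates are compared exactly as parsed (no rounding tolerance).
    """

    def __init__(self, dedupe: str = "per_species", drop_missing_duration: bool = True):
        self.dedupe = dedupe
        self.drop_missing_duration = drop_missing_duration

    def fit(self, X: pd.DataFrame, y=None):
        if self.dedupe not in ("per_species", "per_checklist"):
            raise ValueError(f"dedupe must be 'per_species' or 'per_checklist', got {self.dedupe!r}")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit(X)
        df = X
        removed: dict[str, int] = {}
        n_input = len(df)

        keep = df["complete"].astype(bool)
        removed["complete"] = int((~keep).sum())
        df = df[keep]

        keep = (df["protocol"] == "stationary") | (
            (df["protocol"] == "traveling") & (df["travel_km"] < 5.0))
        removed["protocol"] = int((~keep).sum())
        df = df[keep]

        key = ["lat", "lon", "date"]
        if self.dedupe == "per_species":
            srt = df.sort_values("checklist_id", kind="mergesort")
            kept = srt.drop_duplicates(subset=key + ["species"], keep="first")
            df2 = df.loc[df.index.isin(kept.index)]
        else:
            winner = df.groupby(key, sort=False)["checklist_id"].transform("min")
            df2 = df[df["checklist_id"] == winner]
        removed["unique_location_date"] = len(df) - len(df2)
        df = df2

        keep = df["n_observers"] <= 10
        removed["observers"] = int((~keep).sum())
        df = df[keep]

        grouped = df["group_id"].notna()
        winner = df[grouped].groupby("group_id", sort=False)["checklist_id"].transform("min")
        keep = ~grouped
        keep.loc[winner.index] = df.loc[winner.index, "checklist_id"] == winner
        removed["group_duplicate"] = int((~keep).sum())
        df = df[keep]

        keep = df["duration_h"] <= 5.0
        if not self.drop_missing_duration:
            keep = keep | df["duration_h"].isna()
        removed["duration"] = int((~keep).sum())
        df = df[keep]

        self.report_ = FilterReport(n_input=n_input, removed=removed, n_output=len(df))
        return df.copy()


def filter_checklists(rows: pd.DataFrame, dedupe: str = "per_species") -> tuple[pd.DataFrame, FilterReport]:
    """Apply the six-rule effort filter; return (surviving rows, audit report)."""
    f = ChecklistFilter(dedupe=dedupe)
    out = f.fit(rows).transform(rows)
    return out, f.report_


def resolve_counts(rows: pd.DataFrame, x_policy: str = "drop") -> pd.DataFrame:
    """Resolve presence-only "X" records to numeric counts.

    ``drop`` (default) removes them — a presence-only record carries no
    abundance weight; ``as_one`` recodes them as count 1.
    """
    if x_policy not in ("drop", "as_one"):
        raise ValueError(f"x_policy must be 'drop' or 'as_one', got {x_policy!r}")
    df = rows.copy()
    xmask = df["presence_only"].astype(bool)
    if x_policy == "drop":
        df = df[~xmask]
    else:
        df.loc[xmask, "count"] = 1
        df["presence_only"] = False
    df["count"] = df["count"].astype(int)
    return df


def nonzero_observations(rows: pd.DataFrame, x_policy: str = "drop") -> pd.DataFrame:
    """Keep observations with resolved abundance >= 1 (the centroid inputs)."""
    df = resolve_counts(rows, x_policy=x_policy)
    return df[df["count"] >= 1]
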