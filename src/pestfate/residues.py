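"""Insecticide-residue observation database: load, validate, filter,
summarize.

Observations are rows of a CSV with one measured concentration each:
study, sampling year/months, substrate (soil, sediment, water or air),
collection/extraction/quantification methods, detection and
quantification limits, compound and class, concentration, and
coordinates.  Loading is strict but not destructive: rows violating hard
invariants are rejected into an error report with a reason, never
silently dropped; rows whose coordinates fall outside the Africa
bounding box are kept but flagged as not georeferenced.

The funnel report reproduces the observation-extraction bookkeeping:
total observations, georeferenced observations, per-substrate counts,
distinct compounds and studies, and — optionally filtered to one
compound and a substrate set — the number of unique sampling locations
(distinct coordinate pairs at full stored precision, or rounded to a
chosen number of decimals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SUBSTRATES",
    "AFRICA_BBOX",
    "ResidueDatabase",
    "FunnelReport",
    "load_and_validate",
    "funnel",
]

SUBSTRATES = ("soil", "sediment", "water", "air")

#: (lat_min, lat_max, lon_min, lon_max); configurable per load
AFRICA_BBOX = (-35.0, 38.0, -26.0, 64.0)

MANDATORY_COLUMNS = ("study_id", "substrate", "compound",
                     "concentration", "latitude", "longitude")


@dataclass
class ResidueDatabase:
    """Typed residue table plus the bounding box used for georeferencing."""

    COLUMNS = ("study_id", "year", "months", "substrate",
               "collection_method", "depth_cm", "extraction_method",
               "quantification_method", "detection_limit",
               "quantification_limit", "compound", "compound_class",
               "concentration", "concentration_units",
               "latitude", "longitude")

    table: pd.DataFrame
    bbox: tuple[float, float, float, float] = AFRICA_BBOX

    def __post_init__(self) -> None:
        if "georeferenced" not in self.table.columns:
            self.table = self.table.assign(
                georeferenced=_in_bbox(self.table, self.bbox))

    def __len__(self) -> int:
        return len(self.table)

    def filter(self, compound: str | None = None,
               substrates: Iterable[str] | None = None) -> "ResidueDatabase":
        t = self.table
        if compound is not None:
            t = t[t["compound"] == compound]
        if substrates is not None:
            t = t[t["substrate"].isin(list(substrates))]
        return ResidueDatabase(t.reset_index(drop=True), self.bbox)

    def write(self, path: str | Path) -> None:
        self.table.drop(columns=["georeferenced"]).to_csv(path, index=False)


def _in_bbox(t: pd.DataFrame, bbox) -> pd.Series:
    lat_min, lat_max, lon_min, lon_max = bbox
    return (t["latitude"].between(lat_min, lat_max)
            & t["longitude"].between(lon_min, lon_max)).fillna(False)


@dataclass
class FunnelReport:
    """Observation-extraction summary."""

    total_observations: int
    georeferenced: int
    per_substrate: dict[str, int]
    distinct_compounds: int
    distinct_studies: int
    unique_locations: int
    per_compound: pd.DataFrame = field(repr=False, default=None)  # type: ignore

    def __post_init__(self) -> None:
        if self.georeferenced > self.total_observations:
            raise ValueError("georeferenced count exceeds total")
        if sum(self.per_substrate.values()) > self.total_observations:
            raise ValueError("substrate counts exceed total")

    def to_dict(self) -> dict:
        return {
            "total_observations": self.total_observations,
            "georeferenced": self.georeferenced,
            "per_substrate": dict(self.per_substrate),
            "distinct_compounds": self.distinct_compounds,
            "distinct_studies": self.distinct_studies,
            "unique_locations": self.unique_locations,
        }


def load_and_validate(path: str | Path,
                      column_map: Mapping[str, str] | None = None,
                      bbox=AFRICA_BBOX,
                      ) -> tuple[ResidueDatabase, pd.DataFrame]:
    """Read a residue CSV; return (accepted database, rejected-row report).

    ``column_map`` renames the file's headers onto the canonical schema
    (the deposited files' exact headers vary between sources).  Rejection
    reasons: unknown substrate, negative concentration.  Out-of-bbox or
    missing coordinates only clear the georeferenced flag.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    t = pd.read_csv(path)
    if column_map:
        t = t.rename(columns=dict(column_map))
    missing = [c for c in MANDATORY_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")

    reasons = pd.Series("", index=t.index, dtype=object)
    bad_substrate = ~t["substrate"].isin(SUBSTRATES)
    reasons[bad_substrate] = "unknown substrate: " + t.loc[
        bad_substrate, "substrate"].astype(str)
    conc = pd.to_numeric(t["concentration"], errors="coerce")
    neg = conc.notna() & (conc < 0)
    reasons[neg & (reasons == "")] = "negative concentration"

    rejected = t[reasons != ""].assign(reason=reasons[reasons != ""])
    accepted = t[reasons == ""].reset_index(drop=True)
    db = ResidueDatabase(accepted, bbox)
    return db, rejected.reset_index(drop=True)


def funnel(db: ResidueDatabase, compound: str | None = None,
           substrates: Iterable[str] | None = None,
           location_decimals: int | None = None) -> FunnelReport:
    """Count observations, georeferencing, substrates, compounds, studies
    and unique sampling locations, optionally filtered.

    An unknown compound yields an empty (all-zero) report, not an error.
    Unique locations are distinct (lat, lon) pairs among georeferenced
    rows, at full stored precision unless ``location_decimals`` is given.
    """
    sub = db.filter(compound, substrates)
    t = sub.table
    geo = t[t["georeferenced"]]
    coords = geo[["latitude", "longitude"]]
    if location_decimals is not None:
        coords = coords.round(location_decimals)
    per_compound = (
        t.groupby("compound")
        .agg(observations=("compound", "size"))
        .join(geo.groupby("compound")[["latitude", "longitude"]]
              .apply(lambda g: len(g.drop_duplicates()))
              .rename("unique_locations"))
        .fillna({"unique_locations": 0}).astype(int)
    ) if len(t) else pd.DataFrame(columns=["observations", "unique_locations"])
    return FunnelReport(
        total_observations=len(t),
        georeferenced=int(t["georeferenced"].sum()),
        per_substrate={s: int((t["substrate"] == s).sum()) for s in SUBSTRATES},
        distinct_compounds=int(t["compound"].nunique()),
        distinct_studies=int(t["study_id"].nunique()),
        unique_locations=int(len(coords.drop_duplicates())),
        per_compound=per_compound,
    )
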