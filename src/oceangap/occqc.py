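"""Occurrence-record quality control.

Reduces a raw occurrence table to accepted marine/brackish animal records
with valid coordinates and depths, mirroring the standard cleaning of
OBIS/GBIF extracts: duplicate removal, absence and fossil flags, coordinate
validity, on-land points against a bathymetry raster, depth-versus-bathymetry
consistency with a 50 m margin, a 100 km coordinate-uncertainty ceiling, and
name resolution against a taxon registry (accepted marine/brackish Animalia
only, synonyms mapped to accepted names).

Rules run in a fixed order (dedupe -> flags -> coords -> land -> depth ->
uncertainty -> taxa) so each removed record is attributed to exactly one
first-failing rule and the QC report reconciles exactly:
records_in - sum(removals) = records_out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .rasters import Raster

__all__ = [
    "QCReport", "deduplicate", "filter_flags", "validate_coordinates",
    "on_land_mask", "depth_conflict_mask", "uncertainty_filter",
    "match_taxa", "run_qc",
    "DEPTH_MARGIN_M", "MAX_UNCERTAINTY_M",
]

DEPTH_MARGIN_M = 50.0          # reported depth may exceed bathymetry by this
MAX_UNCERTAINTY_M = 100_000.0  # 100 km coordinate uncertainty ceiling

#: attribution order of removal reasons in the report
RULES = ("duplicate", "absent", "fossil", "bad_coords", "on_land",
         "depth_conflict", "high_uncertainty", "unmatched_taxon",
         "non_marine", "non_animal")

_DUP_KEY = ["raw_name", "latitude", "longitude", "depth", "event_date", "dataset_id"]


@dataclass
class QCReport:
    records_in: int = 0
    records_out: int = 0
    species_out: int = 0
    removed: dict = field(default_factory=lambda: {r: 0 for r in RULES})

    def check(self) -> None:
        if self.records_in - sum(self.removed.values()) != self.records_out:
            raise AssertionError("QC accounting does not reconcile")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse exact duplicates on (name, lat, lon, depth, date, dataset).

    The key deliberately excludes coordinate uncertainty: the same record
    harvested twice often differs only in metadata completeness.  The first
    occurrence is kept.
    """
    return records.drop_duplicates(subset=_DUP_KEY, keep="first")


def filter_flags(records: pd.DataFrame) -> pd.DataFrame:
    """Drop absence records and fossil specimens."""
    status = records["status"].astype(str).str.lower()
    basis = records["basis"].astype(str).str.lower()
    keep = (status != "absent") & (~basis.str.contains("fossil"))
    return records[keep]


def validate_coordinates(records: pd.DataFrame) -> pd.DataFrame:
    """Drop missing/non-finite/out-of-range coordinates; normalize lon 180."""
    lat = pd.to_numeric(records["latitude"], errors="coerce")
    lon = pd.to_numeric(records["longitude"], errors="coerce")
    ok = (np.isfinite(lat) & np.isfinite(lon)
          & (lat >= -90) & (lat <= 90) & (lon >= -180) & (lon <= 180))
    out = records[ok].copy()
    lon = pd.to_numeric(out["longitude"], errors="coerce")
    out.loc[lon == 180.0, "longitude"] = -180.0
    return out


def on_land_mask(records: pd.DataFrame, bathymetry: Raster) -> np.ndarray:
    """True where the raster cell containing the point is land.

    Land cells are nodata or non-positive bathymetry.  Point-in-cell uses
    the floor convention (edges belong to the +lat/+lon side).  Points
    outside the raster domain raise.
    """
    depth = bathymetry.sample(records["latitude"].to_numpy(dtype=float),
                              records["longitude"].to_numpy(dtype=float))
    return ~(np.isfinite(depth) & (depth > 0))


def depth_conflict_mask(records: pd.DataFrame, bathymetry: Raster,
                        margin_m: float = DEPTH_MARGIN_M) -> np.ndarray:
    """True where reported depth exceeds local bathymetry by > margin.

    Strict inequality: depth == bathymetry + margin is kept.  Records with
    no depth are never flagged by this rule.
    """
    d = records["depth"].to_numpy(dtype=float)
    local = bathymetry.sample(records["latitude"].to_numpy(dtype=float),
                              records["longitude"].to_numpy(dtype=float))
    return np.isfinite(d) & np.isfinite(local) & (d > local + margin_m)


def uncertainty_filter(records: pd.DataFrame,
                       max_m: float = MAX_UNCERTAINTY_M) -> pd.DataFrame:
    """Drop records whose coordinate uncertainty exceeds 100 km (strict >);
    records without an uncertainty are kept."""
    unc = pd.to_numeric(records["coord_uncertainty"], errors="coerce")
    return records[~(np.isfinite(unc) & (unc > max_m))]


def match_taxa(records: pd.DataFrame, registry: pd.DataFrame,
               counts: dict | None = None) -> pd.DataFrame:
    """Resolve names against the registry; keep accepted marine/brackish
    Animalia only.

    Matching is exact-string on ``raw_name`` (misspellings are handled only
    when present as registry rows).  Synonyms map to their accepted name,
    whose environment flags and kingdom are used.  ``accepted_species`` is
    populated on survivors.  If ``counts`` is given, removals are tallied
    into its ``unmatched_taxon`` / ``non_marine`` / ``non_animal`` keys.
    """
    acc = registry[registry["status"] == "accepted"].set_index("raw_name")
    reg = registry[registry["status"].isin(["accepted", "synonym"])]
    lut = reg.set_index("raw_name")["accepted_name"]
    resolved = records["raw_name"].map(lut)

    flags = acc.reindex(resolved)
    matched = resolved.notna() & flags["status"].notna().to_numpy()
    marine = (flags["is_marine"].eq(True) | flags["is_brackish"].eq(True)).to_numpy()
    animal = (flags["kingdom"] == "Animalia").to_numpy()

    if counts is not None:
        counts["unmatched_taxon"] += int((~matched).sum())
        counts["non_marine"] += int((matched & ~marine).sum())
        counts["non_animal"] += int((matched & marine & ~animal).sum())
    out = records[matched & marine & animal].copy()
    out["accepted_species"] = resolved[matched & marine & animal]
    return out


def run_qc(records: pd.DataFrame, registry: pd.DataFrame, bathymetry: Raster,
           margin_m: float = DEPTH_MARGIN_M, max_uncertainty_m: float = MAX_UNCERTAINTY_M,
           flag_zero_zero: bool = False) -> tuple[pd.DataFrame, QCReport]:
    """Full QC pipeline with per-rule accounting.

    ``flag_zero_zero`` optionally drops lat=lon=0 points (a common doubtful-
    coordinate heuristic), counted under ``bad_coords``; off by default.
    Idempotent: running the output through QC again removes nothing.
    """
    rep = QCReport(records_in=len(records))
    df = records

    step = deduplicate(df)
    rep.removed["duplicate"] = len(df) - len(step)
    df = step

    status = df["status"].astype(str).str.lower()
    basis = df["basis"].astype(str).str.lower()
    n_absent = int((status == "absent").sum())
    rep.removed["absent"] = n_absent
    rep.removed["fossil"] = int(((status != "absent") & basis.str.contains("fossil")).sum())
    df = filter_flags(df)

    step = validate_coordinates(df)
    if flag_zero_zero:
        zz = (step["latitude"] == 0) & (step["longitude"] == 0)
        step = step[~zz]
    rep.removed["bad_coords"] = len(df) - len(step)
    df = step

    if len(df):
        land = on_land_mask(df, bathymetry)
        rep.removed["on_land"] = int(land.sum())
        df = df[~land]
        conflict = depth_conflict_mask(df, bathymetry, margin_m)
        rep.removed["depth_conflict"] = int(conflict.sum())
        df = df[~conflict]

    step = uncertainty_filter(df, max_uncertainty_m)
    rep.removed["high_uncertainty"] = len(df) - len(step)
    df = step

    df = match_taxa(df, registry, counts=rep.removed)

    rep.records_out = len(df)
    rep.species_out = int(df["accepted_species"].nunique()) if len(df) else 0
    rep.check()
    return df, rep
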