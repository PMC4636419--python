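"""Curation of raw presence records into the analysis occurrence set.

Museum and literature records are noisy: duplicated reports of the same
population, translocated individuals, records outside the study window.
The curation rules here are: (i) keep records inside a date window,
(ii) drop records inside named exclusion zones (e.g. translocations near a
city), (iii) clip to the study area, and (iv) de-duplicate by keeping only
the latest observation among records closer than a radius (default 5 km).

No record is ever deleted: every input record keeps a flag explaining its
fate, so the audit trail reconstructs the input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geodata import LambertAzimuthalEqualArea, DEFAULT_PROJECTION, PointSet, StudyArea

KEPT = "kept"
DROPPED_DATE = "dropped_date"
DROPPED_DUPLICATE = "dropped_duplicate"
DROPPED_EXCLUDED = "dropped_excluded"
DROPPED_OUT_OF_AREA = "dropped_out_of_area"
PARSE_ERROR = "parse_error"

_COLUMNS = ["id", "lon", "lat", "date", "source", "x", "y", "flag", "flag_detail"]


@dataclass
class OccurrenceTable:
    """Presence records with per-record curation flags.

    Wraps a DataFrame with columns ``id, lon, lat, date, source, x, y,
    flag, flag_detail``.  ``date`` is a pandas datetime (NaT when the raw
    string could not be parsed); ``x, y`` are projected km.
    """

    df: pd.DataFrame
    projection: LambertAzimuthalEqualArea = field(default=DEFAULT_PROJECTION)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns: {missing}")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def kept(self) -> pd.DataFrame:
        return self.df[self.df["flag"] == KEPT]

    @property
    def n_kept(self) -> int:
        return int((self.df["flag"] == KEPT).sum())

    def kept_points(self) -> PointSet:
        k = self.kept
        return PointSet(
            x=k["x"].to_numpy(),
            y=k["y"].to_numpy(),
            lon=k["lon"].to_numpy(),
            lat=k["lat"].to_numpy(),
        )

    def copy(self) -> "OccurrenceTable":
        return OccurrenceTable(self.df.copy(), projection=self.projection)

    def to_audit_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def _parse_dates(raw: pd.Series) -> pd.Series:
    """Permissive date parsing; bare years become January 1 of that year."""
    out = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = out.isna()
    if bad.any():
        # year-only entries common in museum data
        years = pd.to_numeric(raw[bad], errors="coerce")
        ok_year = years.notna() & (years >= 1) & (years <= 9999)
        if ok_year.any():
            out.loc[years[ok_year].index] = pd.to_datetime(
                {"year": years[ok_year].astype(int), "month": 1, "day": 1}
            ).to_numpy()
    return out


def load_occurrences(
    path_or_df: str | Path | pd.DataFrame,
    projection: LambertAzimuthalEqualArea = DEFAULT_PROJECTION,
) -> OccurrenceTable:
    """Read a raw occurrence CSV (columns lon, lat, date, source) and project it.

    Records with unparseable dates are flagged ``parse_error``; records with
    missing coordinates likewise.  Everything else starts as ``kept``.
    """
    if isinstance(path_or_df, pd.DataFrame):
        raw = path_or_df.copy()
    else:
        raw = pd.read_csv(path_or_df)
    for col in ("lon", "lat"):
        if col not in raw.columns:
            raise ValueError(f"occurrence input missing column {col!r}")
    df = pd.DataFrame(
        {
            "id": raw["id"] if "id" in raw.columns else np.arange(len(raw)),
            "lon": pd.to_numeric(raw["lon"], errors="coerce"),
            "lat": pd.to_numeric(raw["lat"], errors="coerce"),
            "date": _parse_dates(raw["date"]) if "date" in raw.columns else pd.NaT,
            "source": raw["source"] if "source" in raw.columns else "unknown",
        }
    )
    df["x"] = np.nan
    df["y"] = np.nan
    df["flag"] = KEPT
    df["flag_detail"] = ""

    no_coords = df["lon"].isna() | df["lat"].isna()
    df.loc[no_coords, "flag"] = PARSE_ERROR
    df.loc[no_coords, "flag_detail"] = "missing coordinates"
    bad_date = ~no_coords & df["date"].isna()
    df.loc[bad_date, "flag"] = PARSE_ERROR
    df.loc[bad_date, "flag_detail"] = "unparseable date"

    ok = ~no_coords
    if ok.any():
        x, y = projection.forward(df.loc[ok, "lon"].to_numpy(), df.loc[ok, "lat"].to_numpy())
        df.loc[ok, "x"] = x
        df.loc[ok, "y"] = y
    return OccurrenceTable(df[_COLUMNS], projection=projection)


def from_xy(
    x,
    y,
    dates=None,
    sources: Sequence[str] | str = "synthetic",
    projection: LambertAzimuthalEqualArea = DEFAULT_PROJECTION,
) -> OccurrenceTable:
    """Build an occurrence table directly from projected coordinates."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    n = x.size
    if dates is None:
        dates = ["2000-01-01"] * n
    dates = pd.to_datetime(dates)
    if not hasattr(dates, "__len__") or isinstance(dates, pd.Timestamp):
        dates = pd.DatetimeIndex([dates] * n)
    lon, lat = projection.inverse(x, y)
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "lon": lon,
            "lat": lat,
            "date": pd.DatetimeIndex(dates),
            "source": sources,
            "x": x,
            "y": y,
            "flag": KEPT,
            "flag_detail": "",
        }
    )
    return OccurrenceTable(df[_COLUMNS], projection=projection)


def filter_dates(table: OccurrenceTable, start_year: int, end_year: int) -> OccurrenceTable:
    """Flag kept records whose year falls outside [start_year, end_year]."""
    out = table.copy()
    df = out.df
    kept = df["flag"] == KEPT
    years = df["date"].dt.year
    outside = kept & (years.notna()) & ((years < start_year) | (years > end_year))
    df.loc[outside, "flag"] = DROPPED_DATE
    df.loc[outside, "flag_detail"] = f"outside {start_year}-{end_year}"
    return out


def apply_exclusions(
    table: OccurrenceTable, exclusion_zones: Sequence[tuple[str, "object"]] | Sequence["object"]
) -> OccurrenceTable:
    """Flag kept records inside any exclusion polygon (boundary counts as inside).

    ``exclusion_zones`` is a sequence of shapely polygons or (name, polygon)
    pairs, in projected km.
    """
    import shapely

    out = table.copy()
    df = out.df
    kept_mask = (df["flag"] == KEPT).to_numpy()
    if not kept_mask.any():
        return out
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    for i, zone in enumerate(exclusion_zones):
        if isinstance(zone, tuple):
            name, poly = zone
        else:
            name, poly = f"zone_{i}", zone
        inside = shapely.intersects_xy(poly, x, y) & kept_mask
        df.loc[inside, "flag"] = DROPPED_EXCLUDED
        df.loc[inside, "flag_detail"] = name
        kept_mask &= ~inside
    return out


def clip_to_study_area(table: OccurrenceTable, area: StudyArea) -> OccurrenceTable:
    """Flag kept records outside the study-area polygon."""
    out = table.copy()
    df = out.df
    kept = (df["flag"] == KEPT).to_numpy()
    if not kept.any():
        return out
    inside = area.contains_points(df["x"].to_numpy(), df["y"].to_numpy())
    outside = kept & ~inside
    df.loc[outside, "flag"] = DROPPED_OUT_OF_AREA
    df.loc[outside, "flag_detail"] = "outside study area"
    return out


def deduplicate(table: OccurrenceTable, radius_km: float = 5.0) -> OccurrenceTable:
    """Keep only the latest observation among records overlapping within radius_km.

    Greedy pass over currently-kept records in date-descending order (ties
    broken by input order, first wins): a record survives iff no
    already-accepted record lies within ``radius_km`` (planar projected
    distance).  Idempotent.
    """
    out = table.copy()
    df = out.df
    kept_idx = df.index[df["flag"] == KEPT]
    if len(kept_idx) == 0:
        return out
    sub = df.loc[kept_idx]
    # stable sort: date descending, input order preserved within ties
    order = sub.sort_values("date", ascending=False, kind="stable").index
    accepted_x: list[float] = []
    accepted_y: list[float] = []
    accepted_id: list = []
    for idx in order:
        x, y = df.at[idx, "x"], df.at[idx, "y"]
        if accepted_x:
            d = np.hypot(np.asarray(accepted_x) - x, np.asarray(accepted_y) - y)
            j = int(np.argmin(d))
            if d[j] <= radius_km:
                df.at[idx, "flag"] = DROPPED_DUPLICATE
                df.at[idx, "flag_detail"] = f"within {radius_km} km of id {accepted_id[j]}"
                continue
        accepted_x.append(float(x))
        accepted_y.append(float(y))
        accepted_id.append(df.at[idx, "id"])
    return out


def curate(
    table: OccurrenceTable,
    area: StudyArea,
    start_year: int = 1950,
    end_year: int = 2012,
    dedup_radius_km: float = 5.0,
    exclusion_zones: Sequence = (),
) -> OccurrenceTable:
    """Full curation pipeline: dates -> exclusions -> study area -> de-dup."""
    t = filter_dates(table, start_year, end_year)
    if exclusion_zones:
        t = apply_exclusions(t, exclusion_zones)
    t = clip_to_study_area(t, area)
    t = deduplicate(t, radius_km=dedup_radius_km)
    k = t.kept
    if len(k) >= 2:
        from .geodata import pairwise_distance_km

        pts = t.kept_points()
        d = pairwise_distance_km(pts, pts)
        np.fill_diagonal(d, np.inf)
        assert d.min() > dedup_radius_km, "dedup invariant violated"
    return t
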