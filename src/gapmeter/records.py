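"""Occurrence-record cleaning and assignment to analysis grid cells.

Records travel as :class:`pandas.DataFrame` objects with (at least) the
columns ``species``, ``lat``, ``lon``, ``date`` and ``source``.  ``lat`` and
``lon`` are kept as the *raw strings read from file* so that the
coordinate-precision filter can count decimal digits faithfully
("-46.700" and "-46.7" are different records to that filter even though
they parse to the same float).  Parsed planar/decimal coordinates are added
as float columns ``x`` (from ``lon``) and ``y`` (from ``lat``).

The full pipeline applies the filters in a fixed order — duplicates →
precision → extent → centroid → taxonomy — so each removed record is charged
to exactly one cause and the report counts are additive.
"""

from __future__ import annotations

import math
import re
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry.base import BaseGeometry

__all__ = [
    "CleaningReport",
    "GridIndex",
    "deduplicate",
    "filter_precision",
    "filter_extent",
    "filter_centroids",
    "filter_taxonomy",
    "clean_records",
    "assign_to_grid",
    "normalize_name",
]

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Normalize a species name for matching: trim, collapse whitespace, casefold."""
    return _WS.sub(" ", str(name).strip()).casefold()


def _normalize_coord_string(raw: object) -> str:
    """Canonicalize a raw coordinate string (unicode minus, decimal comma)."""
    s = str(raw).strip().replace("−", "-")
    if "," in s and "." not in s:
        s = s.replace(",", ".")
    return s


def parse_coord(raw: object) -> float:
    """Parse a raw coordinate string to float; NaN if unparseable."""
    try:
        value = float(_normalize_coord_string(raw))
    except (TypeError, ValueError):
        return math.nan
    return value if math.isfinite(value) else math.nan


def count_decimals(raw: object) -> int:
    """Number of digits after the decimal separator in the raw string.

    Counts *written* digits, so trailing zeros count: "-46.700" has three
    decimals, "-46.7" one, "-46" zero.  Unparseable strings report -1.
    """
    s = _normalize_coord_string(raw)
    if math.isnan(parse_coord(s)):
        return -1
    if "." not in s:
        return 0
    return len(s.rsplit(".", 1)[1])


@dataclass
class CleaningReport:
    """Per-filter removal counts for one cleaning run.

    Invariant: ``input - (removed_duplicates + removed_precision +
    removed_extent + removed_centroid + removed_taxonomy) == surviving``.
    """

    input: int = 0
    removed_duplicates: int = 0
    removed_precision: int = 0
    removed_extent: int = 0
    removed_centroid: int = 0
    removed_taxonomy: int = 0
    surviving: int = 0

    def check(self) -> None:
        removed = (
            self.removed_duplicates
            + self.removed_precision
            + self.removed_extent
            + self.removed_centroid
            + self.removed_taxonomy
        )
        if self.input - removed != self.surviving:
            raise AssertionError(f"cleaning report counts do not add up: {self}")

    def to_dict(self) -> dict[str, int]:
        return asdict(self)


def _ensure_parsed(records: pd.DataFrame) -> pd.DataFrame:
    if "x" in records.columns and "y" in records.columns:
        return records
    out = records.copy()
    out["x"] = [parse_coord(v) for v in out["lon"]]
    out["y"] = [parse_coord(v) for v in out["lat"]]
    return out


def deduplicate(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop records duplicating a (species, lat, lon, date) key; keep the first.

    The key uses the normalized species name and the *raw* coordinate strings.
    """
    key = pd.DataFrame(
        {
            "sp": records["species"].map(normalize_name),
            "lat": records["lat"].astype(str).str.strip(),
            "lon": records["lon"].astype(str).str.strip(),
            "date": records["date"].astype(str).str.strip(),
        }
    )
    keep = ~key.duplicated(keep="first")
    return records.loc[keep], int((~keep).sum())


def filter_precision(records: pd.DataFrame, min_decimals: int = 3) -> tuple[pd.DataFrame, int]:
    """Keep records whose raw lat AND lon strings carry >= min_decimals decimals.

    Unparseable coordinate strings are removed here (counted under precision).
    """
    lat_dec = records["lat"].map(count_decimals)
    lon_dec = records["lon"].map(count_decimals)
    keep = (lat_dec >= min_decimals) & (lon_dec >= min_decimals)
    return records.loc[keep], int((~keep).sum())


def filter_extent(records: pd.DataFrame, polygon: BaseGeometry) -> tuple[pd.DataFrame, int]:
    """Keep records inside the study polygon; the boundary counts as inside."""
    if polygon.is_empty or not polygon.is_valid:
        raise ValueError("study polygon is empty or invalid")
    recs = _ensure_parsed(records)
    pts = shapely.points(recs["x"].to_numpy(), recs["y"].to_numpy())
    keep = shapely.covers(polygon, pts) & recs["x"].notna() & recs["y"].notna()
    keep = np.asarray(keep, dtype=bool)
    return recs.loc[keep], int((~keep).sum())


def filter_centroids(
    records: pd.DataFrame,
    centroids: pd.DataFrame | None,
    radius: float = 1000.0,
) -> tuple[pd.DataFrame, int]:
    """Remove records within ``radius`` of any listed centroid (same CRS units).

    ``centroids`` needs columns ``x`` and ``y``; None or empty is the identity.
    """
    if centroids is None or len(centroids) == 0:
        return records, 0
    recs = _ensure_parsed(records)
    tree = cKDTree(np.column_stack([centroids["x"], centroids["y"]]))
    dist, _ = tree.query(np.column_stack([recs["x"], recs["y"]]), k=1)
    keep = dist > radius
    return recs.loc[keep], int((~keep).sum())


def filter_taxonomy(
    records: pd.DataFrame,
    valid_names: list[str],
    synonym_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Canonicalize names via the synonym map; drop names in neither list.

    Raises ``ValueError`` if a synonym maps to a name outside ``valid_names``.
    """
    synonym_map = synonym_map or {}
    canonical = {normalize_name(v): v for v in valid_names}
    syn = {}
    for s, accepted in synonym_map.items():
        if normalize_name(accepted) not in canonical:
            raise ValueError(f"synonym {s!r} maps to non-valid name {accepted!r}")
        syn[normalize_name(s)] = canonical[normalize_name(accepted)]

    def resolve(name: str) -> str | None:
        norm = normalize_name(name)
        if norm in canonical:
            return canonical[norm]
        return syn.get(norm)

    resolved = records["species"].map(resolve)
    keep = resolved.notna()
    out = records.loc[keep].copy()
    out["species"] = resolved.loc[keep]
    return out, int((~keep).sum())


def clean_records(
    records: pd.DataFrame,
    polygon: BaseGeometry,
    valid_names: list[str] | None = None,
    synonym_map: dict[str, str] | None = None,
    centroids: pd.DataFrame | None = None,
    min_decimals: int = 3,
    centroid_radius: float = 1000.0,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Run the full cleaning pipeline in the fixed filter order."""
    report = CleaningReport(input=len(records))
    recs, report.removed_duplicates = deduplicate(records)
    recs, report.removed_precision = filter_precision(recs, min_decimals)
    recs, report.removed_extent = filter_extent(recs, polygon)
    recs, report.removed_centroid = filter_centroids(recs, centroids, centroid_radius)
    if valid_names is not None:
        recs, report.removed_taxonomy = filter_taxonomy(recs, valid_names, synonym_map)
    report.surviving = len(recs)
    report.check()
    return recs, report


@dataclass
class GridIndex:
    """Equal-area analysis grid with half-open cells [x, x+s) x [y, y+s).

    Cells are addressed (row, col) with row = floor((y - y0)/s): row 0 is the
    *bottom* row.  ``n_rows``/``n_cols`` bound the extent when given.
    """

    x0: float
    y0: float
    cell_size: float = 1000.0
    n_rows: int | None = None
    n_cols: int | None = None

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        row = math.floor((y - self.y0) / self.cell_size)
        col = math.floor((x - self.x0) / self.cell_size)
        if self.n_rows is not None and not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        return row, col

    def cells_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rows = np.floor((np.asarray(y) - self.y0) / self.cell_size).astype(int)
        cols = np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(int)
        if self.n_rows is not None:
            bad = (rows < 0) | (rows >= self.n_rows) | (cols < 0) | (cols >= self.n_cols)
            if bad.any():
                raise ValueError(f"{int(bad.sum())} point(s) outside grid extent")
        return rows, cols

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x0 + (col + 0.5) * self.cell_size,
            self.y0 + (row + 0.5) * self.cell_size,
        )


def assign_to_grid(records: pd.DataFrame, grid: GridIndex) -> dict[tuple[int, int], pd.DataFrame]:
    """Map grid cell -> records falling in it; cells without records are absent."""
    recs = _ensure_parsed(records)
    if recs[["x", "y"]].isna().any().any():
        raise ValueError("records with unparseable coordinates reached grid assignment")
    rows, cols = grid.cells_of(recs["x"].to_numpy(), recs["y"].to_numpy())
    out: dict[tuple[int, int], pd.DataFrame] = {}
    keys = pd.MultiIndex.from_arrays([rows, cols])
    for cell, sub in recs.groupby(keys):
        out[cell] = sub
    return out
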