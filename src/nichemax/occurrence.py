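"""Occurrence ingestion and spatial thinning.

Occurrence records arrive as delimited text with longitude/latitude
columns (decimal degrees, WGS84).  Cleaning drops rows without parseable
coordinates and collapses exact duplicates; thinning then enforces a
minimum great-circle distance (default 5 km) between retained points by
a greedy first-come scan, which discards any point closer than the
radius to an already-kept point.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geodesy import haversine_km

SOURCES = ("field", "herbarium", "literature", "synthetic")

_LON_ALIASES = ("longitude", "lon", "long", "x", "decimallongitude")
_LAT_ALIASES = ("latitude", "lat", "y", "decimallatitude")


class EmptyOccurrenceError(ValueError):
    """No parseable occurrence rows."""


@dataclass
class OccurrenceSet:
    """Ordered cleaned presence points.

    ``records`` has columns species, longitude, latitude, source.
    Cleaning counters describe what was discarded on ingestion.
    """

    records: pd.DataFrame
    n_dropped_invalid: int = 0
    n_duplicates_collapsed: int = 0
    n_thinned_out: int = 0
    thin_radius_km: float | None = None

    def __post_init__(self) -> None:
        df = self.records
        for col in ("longitude", "latitude"):
            if col not in df.columns:
                raise ValueError(f"occurrence table lacks '{col}' column")
        if "species" not in df.columns:
            df = df.assign(species="unknown")
        if "source" not in df.columns:
            df = df.assign(source="synthetic")
        bad_lon = (df["longitude"] < -180) | (df["longitude"] > 180)
        bad_lat = (df["latitude"] < -90) | (df["latitude"] > 90)
        if bool((bad_lon | bad_lat).any()):
            raise ValueError("coordinates outside valid lon/lat ranges")
        self.records = df[["species", "longitude", "latitude", "source"]
                          ].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def longitude(self) -> np.ndarray:
        return self.records["longitude"].to_numpy(dtype=float)

    @property
    def latitude(self) -> np.ndarray:
        return self.records["latitude"].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return self.records.copy()

    def write_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def _find_column(columns: list[str], aliases: tuple[str, ...]) -> str | None:
    lowered = {c.lower().strip(): c for c in columns}
    for a in aliases:
        if a in lowered:
            return lowered[a]
    return None


def read_occurrences(path: str | Path, species: str | None = None) -> OccurrenceSet:
    """Read and clean a delimited occurrence file.

    Rows with missing or unparseable coordinates are dropped and counted;
    exact duplicate (lon, lat) pairs are collapsed to the first record.
    Raises :class:`EmptyOccurrenceError` when nothing parseable remains.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    lon_col = _find_column(list(df.columns), _LON_ALIASES)
    lat_col = _find_column(list(df.columns), _LAT_ALIASES)
    if lon_col is None or lat_col is None:
        raise EmptyOccurrenceError(
            f"{path}: no longitude/latitude columns among {list(df.columns)}")
    lon = pd.to_numeric(df[lon_col], errors="coerce")
    lat = pd.to_numeric(df[lat_col], errors="coerce")
    ok = lon.notna() & lat.notna() & lon.between(-180, 180) & lat.between(-90, 90)
    n_dropped = int((~ok).sum())
    clean = pd.DataFrame({
        "species": df["species"] if "species" in df.columns else (species or "unknown"),
        "longitude": lon,
        "latitude": lat,
        "source": df["source"] if "source" in df.columns else "synthetic",
    })[ok]
    before = len(clean)
    clean = clean.drop_duplicates(subset=["longitude", "latitude"], keep="first")
    n_dup = before - len(clean)
    if clean.empty:
        raise EmptyOccurrenceError(f"{path}: no parseable occurrence rows")
    return OccurrenceSet(clean.reset_index(drop=True),
                         n_dropped_invalid=n_dropped,
                         n_duplicates_collapsed=n_dup)


def thin(occ: OccurrenceSet, radius_km: float = 5.0) -> OccurrenceSet:
    """Greedy spatial thinning at a minimum great-circle distance.

    Scans points in input order; a point is kept iff it lies at least
    ``radius_km`` from every already-kept point (strictly closer points
    are discarded).  The result preserves input order, is a subset of the
    input, and the operation is idempotent.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    lon, lat = occ.longitude, occ.latitude
    kept_idx: list[int] = []
    for i in range(len(occ)):
        if not kept_idx:
            kept_idx.append(i)
            continue
        d = haversine_km(lon[kept_idx], lat[kept_idx], lon[i], lat[i])
        if np.min(d) >= radius_km:
            kept_idx.append(i)
    records = occ.records.iloc[kept_idx].reset_index(drop=True)
    return OccurrenceSet(records,
                         n_dropped_invalid=occ.n_dropped_invalid,
                         n_duplicates_collapsed=occ.n_duplicates_collapsed,
                         n_thinned_out=len(occ) - len(kept_idx),
                         thin_radius_km=radius_km)
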