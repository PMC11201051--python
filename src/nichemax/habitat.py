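"""Habitat classification, area accounting, range change, and centroids.

Suitability maps are cut into four classes — unsuitable [0, 0.1), low
[0.1, 0.3), medium [0.3, 0.5), high [0.5, 1] — and per-class areas are
accumulated on the sphere (cell area depends on latitude only) and
reported in ×10⁴ km² with signed deltas against a baseline period.  The
presence/absence matrix uses the strict p > 0.5 rule, range changes are
the per-cell (current, future) algebra expansion/retention/contraction,
and the suitable-range centroid is the area-weighted mean of presence
cell centres, compared across periods by great-circle distance and
initial bearing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geodesy import band_area_km2, haversine_km, initial_bearing_deg
from .grid_io import AlignmentError, EnvGrid, GridHeader

DEFAULT_THRESHOLDS = (0.1, 0.3, 0.5)
CLASS_NAMES = ("unsuitable", "low", "medium", "high")
PRESENCE_THRESHOLD = 0.5
CHANGE_CODES = {"absent": 0, "expansion": 1, "retention": 2, "contraction": 3}


def cell_area_km2(header: GridHeader, row: int) -> float:
    """Area of one cell in row ``row`` (row 0 = north), in km²."""
    if not 0 <= row < header.nrows:
        raise ValueError(f"row {row} outside grid of {header.nrows} rows")
    lat_top = header.yllcorner + (header.nrows - row) * header.cellsize
    return float(band_area_km2(lat_top - header.cellsize, lat_top,
                               header.cellsize))


def _row_areas(header: GridHeader) -> np.ndarray:
    lat_top = header.yllcorner + (header.nrows - np.arange(header.nrows)) \
        * header.cellsize
    return np.asarray(band_area_km2(lat_top - header.cellsize, lat_top,
                                    header.cellsize))


def _masked_area(values_mask: np.ndarray, header: GridHeader) -> float:
    """Total km² of cells where the boolean mask is True."""
    per_row = _row_areas(header)
    return float((values_mask.sum(axis=1) * per_row).sum())


@dataclass
class SuitabilityClassification:
    """4-class habitat raster (codes 0..3, nodata preserved)."""

    class_grid: EnvGrid
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS

    def counts(self) -> dict[str, int]:
        v = self.class_grid.values
        return {name: int(np.nansum(v == code))
                for code, name in enumerate(CLASS_NAMES)}


def classify(suitability: EnvGrid,
             thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
             ) -> SuitabilityClassification:
    """Band a logistic suitability map into the four habitat classes.

    Half-open bands at (t1, t2, t3); p = t3 (0.5) falls in the high
    class.  Values outside [0, 1] raise a validation error.
    """
    v = suitability.values
    finite = ~np.isnan(v)
    if np.any((v[finite] < 0) | (v[finite] > 1)):
        raise ValueError("suitability values must lie in [0, 1]")
    t1, t2, t3 = thresholds
    out = np.full_like(v, np.nan)
    out[finite & (v < t1)] = 0
    out[finite & (v >= t1) & (v < t2)] = 1
    out[finite & (v >= t2) & (v < t3)] = 2
    out[finite & (v >= t3)] = 3
    grid = EnvGrid(suitability.header, f"{suitability.name}_class", out)
    return SuitabilityClassification(grid, thresholds)


@dataclass
class AreaSummary:
    """Per-class habitat areas in ×10⁴ km² (full precision internally).

    ``total`` is the suitable area low + medium + high; deltas are
    signed differences against a named baseline, "+" meaning increase.
    """

    unsuitable: float
    low: float
    medium: float
    high: float
    period: str = ""
    baseline_period: str | None = None
    deltas: dict[str, float] | None = None

    @property
    def total(self) -> float:
        return self.low + self.medium + self.high

    def as_dict(self) -> dict[str, float]:
        return {"unsuitable": self.unsuitable, "low": self.low,
                "medium": self.medium, "high": self.high, "total": self.total}

    def delta_vs(self, baseline: "AreaSummary") -> "AreaSummary":
        deltas = {k: self.as_dict()[k] - baseline.as_dict()[k]
                  for k in ("unsuitable", "low", "medium", "high", "total")}
        return AreaSummary(self.unsuitable, self.low, self.medium, self.high,
                           period=self.period,
                           baseline_period=baseline.period or "baseline",
                           deltas=deltas)

    def to_row(self) -> dict[str, str]:
        """Table row in the field's conventional format: 2-decimal areas
        with the parenthesised signed delta."""
        def fmt(key: str) -> str:
            a = f"{self.as_dict()[key]:.2f}"
            if self.deltas is None:
                return a
            return f"{a} ({self.deltas[key]:+.2f})"
        return {"period": self.period,
                "non_suitable": fmt("unsuitable"), "low_suitable": fmt("low"),
                "medium_suitable": fmt("medium"), "high_suitable": fmt("high"),
                "total_suitable": fmt("total")}


def class_areas(classification: SuitabilityClassification,
                baseline: AreaSummary | None = None,
                period: str = "") -> AreaSummary:
    """Sum spherical cell areas per habitat class, in ×10⁴ km²."""
    v = classification.class_grid.values
    header = classification.class_grid.header
    areas = [_masked_area(v == code, header) / 1e4
             for code in range(len(CLASS_NAMES))]
    summary = AreaSummary(*areas, period=period)
    if baseline is not None:
        summary = summary.delta_vs(baseline)
    return summary


@dataclass
class BinaryRangeMap:
    """(0,1) presence–absence matrix at the strict p > 0.5 rule."""

    grid: EnvGrid
    threshold: float = PRESENCE_THRESHOLD

    @property
    def header(self) -> GridHeader:
        return self.grid.header

    @property
    def presence(self) -> np.ndarray:
        return self.grid.values == 1

    def area_1e4km2(self) -> float:
        return _masked_area(self.presence, self.header) / 1e4


def binary_map(suitability: EnvGrid,
               threshold: float = PRESENCE_THRESHOLD) -> BinaryRangeMap:
    """Presence where suitability strictly exceeds the threshold."""
    v = suitability.values
    out = np.where(np.isnan(v), np.nan, (v > threshold).astype(float))
    return BinaryRangeMap(EnvGrid(suitability.header,
                                  f"{suitability.name}_range", out), threshold)


@dataclass
class ChangeMap:
    """Expansion/retention/contraction between two binary range maps.

    Areas in ×10⁴ km²; net change = expansion − contraction.  The
    identities retention + contraction = current area and
    retention + expansion = future area hold exactly.
    """

    grid: EnvGrid
    expansion: float
    retention: float
    contraction: float
    current_period: str = "current"
    future_period: str = "future"

    @property
    def net(self) -> float:
        return self.expansion - self.contraction

    def to_row(self) -> dict[str, float | str]:
        return {"period": self.future_period,
                "expansion": round(self.expansion, 2),
                "retention": round(self.retention, 2),
                "contraction": round(self.contraction, 2),
                "net_change": round(self.net, 2)}


def change_map(current: BinaryRangeMap, future: BinaryRangeMap,
               current_period: str = "current",
               future_period: str = "future") -> ChangeMap:
    """Per-cell range algebra: (0,0) absent, (0,1) expansion,
    (1,1) retention, (1,0) contraction."""
    if not current.header.approx_equal(future.header):
        raise AlignmentError("current and future range maps differ in header")
    c, f = current.grid.values, future.grid.values
    valid = ~(np.isnan(c) | np.isnan(f))
    out = np.full_like(c, np.nan)
    out[valid] = CHANGE_CODES["absent"]
    exp = valid & (c == 0) & (f == 1)
    ret = valid & (c == 1) & (f == 1)
    con = valid & (c == 1) & (f == 0)
    out[exp] = CHANGE_CODES["expansion"]
    out[ret] = CHANGE_CODES["retention"]
    out[con] = CHANGE_CODES["contraction"]
    header = current.header
    grid = EnvGrid(header, f"change_{future_period}", out)
    return ChangeMap(grid,
                     expansion=_masked_area(exp, header) / 1e4,
                     retention=_masked_area(ret, header) / 1e4,
                     contraction=_masked_area(con, header) / 1e4,
                     current_period=current_period,
                     future_period=future_period)


@dataclass(frozen=True)
class Centroid:
    longitude: float
    latitude: float
    period: str = ""


@dataclass(frozen=True)
class MigrationVector:
    """Displacement of the range centroid between two periods."""

    origin: Centroid
    destination: Centroid
    distance_km: float
    bearing_deg: float


class EmptyRangeError(ValueError):
    """Binary range contains no presence cell."""


def centroid(range_map: BinaryRangeMap, area_weighted: bool = True,
             period: str = "") -> Centroid:
    """Geometric centre of the presence cells.

    By default each cell centre is weighted by its spherical area so
    lower-latitude (larger) cells pull the centroid toward them; the
    unweighted mean of cell centres is available for comparison.
    """
    pres = range_map.presence
    if not pres.any():
        raise EmptyRangeError("no presence cells in range map")
    header = range_map.header
    rows, cols = np.nonzero(pres)
    lons = header.xllcorner + (cols + 0.5) * header.cellsize
    lats = header.yllcorner + (header.nrows - rows - 0.5) * header.cellsize
    w = _row_areas(header)[rows] if area_weighted else np.ones_like(lons)
    return Centroid(float(np.average(lons, weights=w)),
                    float(np.average(lats, weights=w)), period=period)


def migration_vector(a: Centroid, b: Centroid) -> MigrationVector:
    """Great-circle distance (km) and initial bearing from a to b."""
    d = haversine_km(a.longitude, a.latitude, b.longitude, b.latitude)
    brg = initial_bearing_deg(a.longitude, a.latitude, b.longitude, b.latitude)
    return MigrationVector(a, b, float(d), brg)
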