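"""ESRI ASCII grid I/O and co-registered raster stacks.

The package's raster currency is the plain-text ESRI ASCII grid (.asc):
six header lines (ncols, nrows, xllcorner/xllcenter, yllcorner/yllcenter,
cellsize, NODATA_value) followed by ``nrows`` rows of ``ncols`` numbers,
row 0 being the NORTHERNMOST row.  Internally nodata cells are stored as
NaN; the header's sentinel is used on write.

Coordinate convention: cell (row r, col c) has centre
``lon = xll + (c + 0.5)·cellsize``, ``lat = yll + (nrows − r − 0.5)·cellsize``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

HEADER_TOL = 1e-9  # degrees; headers equal field-by-field within this


class AscFormatError(ValueError):
    """Malformed ESRI ASCII grid file."""


class AlignmentError(ValueError):
    """Layers with incompatible georeferencing cannot be stacked."""


@dataclass(frozen=True)
class GridHeader:
    """Georeferencing of a regular lon/lat grid with square cells."""

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    def approx_equal(self, other: "GridHeader", tol: float = HEADER_TOL) -> bool:
        return (self.ncols == other.ncols
                and self.nrows == other.nrows
                and abs(self.xllcorner - other.xllcorner) <= tol
                and abs(self.yllcorner - other.yllcorner) <= tol
                and abs(self.cellsize - other.cellsize) <= tol)

    # -- geometry helpers -------------------------------------------------
    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.xllcorner + (col + 0.5) * self.cellsize
        lat = self.yllcorner + (self.nrows - row - 0.5) * self.cellsize
        return lon, lat

    def col_centers(self) -> np.ndarray:
        return self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize

    def row_centers(self) -> np.ndarray:
        return self.yllcorner + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize

    def cell_index(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Row/col of the cell containing the point, half-open rule.

        x ∈ [xll + j·cs, xll + (j+1)·cs): lower/left edge inclusive; the
        analogous rule applies to y.  Returns None outside the grid.
        """
        cs = self.cellsize
        fx = (lon - self.xllcorner) / cs
        fy = (lat - self.yllcorner) / cs
        if fx < 0 or fy < 0:
            return None
        col = int(np.floor(fx))
        row_from_bottom = int(np.floor(fy))
        if col >= self.ncols or row_from_bottom >= self.nrows:
            return None
        return self.nrows - 1 - row_from_bottom, col


@dataclass
class EnvGrid:
    """One environmental raster layer; nodata stored as NaN."""

    header: GridHeader
    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.header.nrows, self.header.ncols):
            raise ValueError(
                f"layer '{self.name}': values shape {self.values.shape} does not "
                f"match header ({self.header.nrows}, {self.header.ncols})")
        finite = np.isfinite(self.values) | np.isnan(self.values)
        if not finite.all():
            raise ValueError(f"layer '{self.name}': non-finite non-nodata values")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def with_values(self, values: np.ndarray, name: str | None = None) -> "EnvGrid":
        return EnvGrid(self.header, self.name if name is None else name, values)

    def allclose(self, other: "EnvGrid", tol: float = 1e-9) -> bool:
        return (self.header.approx_equal(other.header)
                and np.allclose(self.values, other.values, atol=tol, equal_nan=True))


def read_asc(path: str | Path, name: str | None = None) -> EnvGrid:
    """Read an ESRI ASCII grid.

    Accepts both the ``xllcorner`` and ``xllcenter`` dialects (centre
    coordinates are converted to corner by subtracting cellsize/2).
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    header_keys = ("ncols", "nrows", ("xllcorner", "xllcenter"),
                   ("yllcorner", "yllcenter"), "cellsize", "nodata_value")
    raw: dict[str, float] = {}
    n_header = 0
    for expect, line in zip(header_keys, lines):
        parts = line.split()
        if len(parts) != 2:
            raise AscFormatError(f"{path}: malformed header line {line!r}")
        key = parts[0].lower()
        accepted = expect if isinstance(expect, tuple) else (expect,)
        if key not in accepted:
            raise AscFormatError(
                f"{path}: expected header key {' or '.join(accepted)!r}, got {key!r}")
        try:
            raw[key] = float(parts[1])
        except ValueError as exc:
            raise AscFormatError(f"{path}: unparseable value for {key!r}") from exc
        n_header += 1
    if n_header < 6:
        raise AscFormatError(f"{path}: truncated header ({n_header} of 6 lines)")

    ncols, nrows = int(raw["ncols"]), int(raw["nrows"])
    cellsize = raw["cellsize"]
    if "xllcenter" in raw:
        raw["xllcorner"] = raw["xllcenter"] - cellsize / 2.0
    if "yllcenter" in raw:
        raw["yllcorner"] = raw["yllcenter"] - cellsize / 2.0
    header = GridHeader(ncols=ncols, nrows=nrows, xllcorner=raw["xllcorner"],
                        yllcorner=raw["yllcorner"], cellsize=cellsize,
                        nodata_value=raw["nodata_value"])
    body = "\n".join(lines[6:])
    try:
        flat = np.loadtxt(io.StringIO(body), dtype=float).ravel()
    except ValueError as exc:
        raise AscFormatError(f"{path}: unparseable grid body: {exc}") from exc
    if flat.size != nrows * ncols:
        raise AscFormatError(
            f"{path}: body has {flat.size} values, header implies {nrows * ncols}")
    values = flat.reshape(nrows, ncols)
    values[values == header.nodata_value] = np.nan
    return EnvGrid(header, name if name is not None else path.stem, values)


def write_asc(grid: EnvGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid; always the 'xllcorner' dialect.

    Values are serialised with 10 significant digits so probabilities in
    [0, 1] round-trip within 1e-9.
    """
    h = grid.header
    out = grid.values.copy()
    out[np.isnan(out)] = h.nodata_value
    with open(path, "w") as fh:
        fh.write(f"ncols {h.ncols}\n")
        fh.write(f"nrows {h.nrows}\n")
        fh.write(f"xllcorner {h.xllcorner:.17g}\n")
        fh.write(f"yllcorner {h.yllcorner:.17g}\n")
        fh.write(f"cellsize {h.cellsize:.17g}\n")
        fh.write(f"NODATA_value {h.nodata_value:.17g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.10g}" for v in row))
            fh.write("\n")


@dataclass
class GridStack:
    """Named, co-registered collection of layers sharing one header.

    ``mask`` marks cells that are valid (non-nodata) in every layer.
    """

    layers: dict[str, EnvGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a stack needs at least one layer")
        first = next(iter(self.layers.values()))
        for name, g in self.layers.items():
            if not g.header.approx_equal(first.header):
                raise AlignmentError(f"layer '{name}' header differs from "
                                     f"'{first.name}'")
        if not self.mask.any():
            raise ValueError("stack has no valid cell (mask empty)")

    @property
    def header(self) -> GridHeader:
        return next(iter(self.layers.values())).header

    @property
    def names(self) -> list[str]:
        return list(self.layers.keys())

    @property
    def mask(self) -> np.ndarray:
        m = None
        for g in self.layers.values():
            m = g.valid_mask if m is None else (m & g.valid_mask)
        return m

    def subset(self, names: Iterable[str]) -> "GridStack":
        names = list(names)
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return GridStack({n: self.layers[n] for n in names})

    def to_table(self) -> pd.DataFrame:
        """Valid-cell values, one row per masked cell, one column per layer."""
        m = self.mask
        data = {n: g.values[m] for n, g in self.layers.items()}
        rows, cols = np.nonzero(m)
        df = pd.DataFrame(data)
        df.insert(0, "row", rows)
        df.insert(1, "col", cols)
        return df


def align_stack(grids: list[EnvGrid]) -> GridStack:
    """Co-register layers into a stack, preserving insertion order.

    Raises :class:`AlignmentError` naming both layers and the first
    differing header field.
    """
    if not grids:
        raise ValueError("need at least one grid")
    ref = grids[0]
    layers: dict[str, EnvGrid] = {}
    for g in grids:
        for fld in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            a, b = getattr(ref.header, fld), getattr(g.header, fld)
            if abs(float(a) - float(b)) > HEADER_TOL:
                raise AlignmentError(
                    f"layers '{ref.name}' and '{g.name}' differ in {fld}: {a} vs {b}")
        if g.name in layers:
            raise AlignmentError(f"duplicate layer name '{g.name}'")
        layers[g.name] = g
    return GridStack(layers)


def extract_values(stack: GridStack, points: "pd.DataFrame | object"
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample every layer at each occurrence point.

    Each point maps to the cell containing it under the half-open rule
    (lower/left edge inclusive).  Points outside the grid or on masked
    cells go to the rejection table with a reason — they are data, not
    errors.

    Returns ``(values, rejections)``; ``values`` has lon, lat, row, col
    plus one column per layer.
    """
    df = points.to_frame() if hasattr(points, "to_frame") else pd.DataFrame(points)
    header = stack.header
    mask = stack.mask
    accepted: list[dict] = []
    rejected: list[dict] = []
    for i, (lon, lat) in enumerate(zip(df["longitude"], df["latitude"])):
        idx = header.cell_index(float(lon), float(lat))
        if idx is None:
            rejected.append({"index": i, "longitude": lon, "latitude": lat,
                             "reason": "outside grid"})
            continue
        r, c = idx
        if not mask[r, c]:
            rejected.append({"index": i, "longitude": lon, "latitude": lat,
                             "reason": "nodata cell"})
            continue
        rec = {"longitude": lon, "latitude": lat, "row": r, "col": c}
        for name, g in stack.layers.items():
            rec[name] = g.values[r, c]
        accepted.append(rec)
    cols = ["longitude", "latitude", "row", "col", *stack.names]
    values = pd.DataFrame(accepted, columns=cols)
    rejections = pd.DataFrame(rejected,
                              columns=["index", "longitude", "latitude", "reason"])
    return values, rejections
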