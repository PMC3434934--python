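"""Regular latitude/longitude grids in ESRI ASCII (.asc) format.

A :class:`Raster` is a single gridded variable on a regular WGS84
lat/lon grid; a :class:`RasterStack` is a set of aligned rasters, one
per bioclimatic variable.  Cells are addressed by (row, col) with row 0
at the northern edge, and a point is assigned to a cell by half-open
bounds [west, east) x [south, north) so no point can land in two cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Raster", "RasterStack", "read_ascii_grid", "write_ascii_grid", "GridAlignmentError"]


class GridAlignmentError(ValueError):
    """Raised when rasters that must share a grid do not."""


@dataclass
class Raster:
    """One variable on a regular lat/lon grid.

    data is a (nrows, ncols) float array with row 0 the northernmost
    row; NODATA is represented as NaN in memory.
    """

    data: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def west(self) -> float:
        return self.xllcorner

    @property
    def south(self) -> float:
        return self.yllcorner

    @property
    def east(self) -> float:
        return self.xllcorner + self.ncols * self.cellsize

    @property
    def north(self) -> float:
        return self.yllcorner + self.nrows * self.cellsize

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.data.shape == other.data.shape
            and math.isclose(self.xllcorner, other.xllcorner, abs_tol=1e-9)
            and math.isclose(self.yllcorner, other.yllcorner, abs_tol=1e-9)
            and math.isclose(self.cellsize, other.cellsize, rel_tol=1e-12)
        )

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing the point, or None if outside.

        Bounds are half-open: [west, east) x [south, north).
        """
        if not (self.west <= lon < self.east and self.south <= lat < self.north):
            return None
        col = int((lon - self.west) / self.cellsize)
        row_from_south = int((lat - self.south) / self.cellsize)
        row = self.nrows - 1 - row_from_south
        # guard against float edge effects at the last cell boundary
        col = min(max(col, 0), self.ncols - 1)
        row = min(max(row, 0), self.nrows - 1)
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (row, col)."""
        lon = self.west + (col + 0.5) * self.cellsize
        lat = self.north - (row + 0.5) * self.cellsize
        return lon, lat


class RasterStack:
    """Aligned rasters, one per variable, in a fixed variable order."""

    def __init__(self, rasters: dict[str, Raster]):
        if not rasters:
            raise ValueError("empty raster stack")
        self.names = list(rasters.keys())
        self.rasters = rasters
        ref = rasters[self.names[0]]
        for name in self.names[1:]:
            if not ref.same_grid(rasters[name]):
                raise GridAlignmentError(
                    f"raster {name!r} is not aligned with {self.names[0]!r}"
                )
        self.grid = ref

    def __len__(self) -> int:
        return len(self.names)

    def values_at(self, row: int, col: int) -> np.ndarray:
        """Climate vector at one cell (NaN where a variable is NODATA)."""
        return np.array([self.rasters[n].data[row, col] for n in self.names])

    def as_array(self) -> np.ndarray:
        """(nvars, nrows, ncols) array in stack variable order."""
        return np.stack([self.rasters[n].data for n in self.names])

    @classmethod
    def from_dir(cls, directory: str | Path, names: list[str] | None = None) -> "RasterStack":
        """Load every ``*.asc`` in a directory (sorted), or the named subset."""
        directory = Path(directory)
        if names is None:
            paths = sorted(directory.glob("*.asc"))
            names = [p.stem for p in paths]
        else:
            paths = [directory / f"{n}.asc" for n in names]
        if not paths:
            raise FileNotFoundError(f"no .asc rasters in {directory}")
        return cls({n: read_ascii_grid(p) for n, p in zip(names, paths)})


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                       "yllcenter", "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {req!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cellsize = header["cellsize"]
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:  # cell-center registration
        xll = header["xllcenter"] - cellsize / 2
        yll = header["yllcenter"] - cellsize / 2
    data = np.array([v for r in rows for v in r], dtype=float).reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    data[data == nodata] = np.nan
    return Raster(data, xll, yll, cellsize, nodata)


def write_ascii_grid(raster: Raster, path: str | Path, fmt: str = "%.6g") -> None:
    """Write an ESRI ASCII grid; NaN cells are written as NODATA."""
    data = np.where(np.isnan(raster.data), raster.nodata, raster.data)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xllcorner:.10g}\n")
        fh.write(f"yllcorner {raster.yllcorner:.10g}\n")
        fh.write(f"cellsize {raster.cellsize:.10g}\n")
        fh.write(f"NODATA_value {raster.nodata:.10g}\n")
        for row in data:
            fh.write(" ".join(fmt % v for v in row) + "\n")
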