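"""Minimal planar raster container with plain-text (ESRI ASCII grid) I/O.

All rasters in this package live on a single square grid in projected,
metre-based coordinates.  Rows are stored south-to-north (row 0 is the
southernmost row); the ASCII-grid serialisation flips rows, since that
format lists the northernmost row first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid", "Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class Grid:
    """Geometry of a raster: lower-left corner, cell size (m), shape."""

    x0: float
    y0: float
    cell: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("degenerate grid")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer cell edges."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell,
            self.y0 + self.nrows * self.cell,
        )

    @property
    def cell_area_m2(self) -> float:
        return self.cell * self.cell

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x (per column) and y (per row) cell-centre coords."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.y0 + (np.arange(self.nrows) + 0.5) * self.cell
        return xs, ys

    def centre_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = self.cell_centres()
        return np.meshgrid(xs, ys)  # shape (nrows, ncols) each

    def index_of(self, x, y, clip: bool = False):
        """(row, col) of the cell containing each point.

        With ``clip=False`` out-of-extent points raise; with ``clip=True``
        they are clamped to the border cells.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell).astype(int)
        row = np.floor((y - self.y0) / self.cell).astype(int)
        # the outer boundary is closed: points exactly on the max edge
        # belong to the border cells
        xmin, ymin, xmax, ymax = self.extent
        col = np.where((col == self.ncols) & (x == xmax), self.ncols - 1, col)
        row = np.where((row == self.nrows) & (y == ymax), self.nrows - 1, row)
        if clip:
            col = np.clip(col, 0, self.ncols - 1)
            row = np.clip(row, 0, self.nrows - 1)
        else:
            bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
            if np.any(bad):
                idx = np.flatnonzero(np.atleast_1d(bad))
                raise ValueError(
                    f"{idx.size} point(s) fall outside the raster extent "
                    f"(first offender index {idx[0]})"
                )
        return row, col

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)


@dataclass
class Raster:
    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"raster values shape {self.values.shape} does not match "
                f"grid shape {self.grid.shape}"
            )

    def sample(self, x, y) -> np.ndarray:
        """Nearest-cell lookup at point coordinates (metres)."""
        row, col = self.grid.index_of(x, y)
        return self.values[row, col]


def write_ascii_grid(raster: Raster, path, nodata: float = -9999.0) -> None:
    g = raster.grid
    vals = np.where(np.isfinite(raster.values), raster.values, nodata)
    header = (
        f"ncols {g.ncols}\n"
        f"nrows {g.nrows}\n"
        f"xllcorner {g.x0!r}\n"
        f"yllcorner {g.y0!r}\n"
        f"cellsize {g.cell!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals[::-1], fmt="%.10g")


def read_ascii_grid(path) -> Raster:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)[::-1].copy()
    nodata = header.get("nodata_value")
    if nodata is not None:
        vals[vals == nodata] = np.nan
    grid = Grid(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell=header["cellsize"],
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
    )
    return Raster(grid, vals)
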