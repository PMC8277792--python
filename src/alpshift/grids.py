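"""Regular single-band grids on a planar coordinate system.

All layers in a study share one geometry: square cells of side ``cell_size``
(map units, metres), origin ``(x0, y0)`` at the lower-left corner of the grid,
row index increasing northwards and column index increasing eastwards.
Cell centres are at ``x0 + (col + 0.5) * cell_size`` etc.  Nodata cells carry
the sentinel value (default -9999) in files and ``nan`` in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0


@dataclass
class Grid:
    """A single-band raster: 2-D float array plus geometry."""

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise ValueError("grid must be 2-D with at least 2x2 cells")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    def x_coords(self) -> np.ndarray:
        """Cell-centre x coordinates, west to east."""
        x0 = self.origin[0]
        return x0 + (np.arange(self.nx) + 0.5) * self.cell_size

    def y_coords(self) -> np.ndarray:
        """Cell-centre y coordinates, south to north (row 0 is southernmost)."""
        y0 = self.origin[1]
        return y0 + (np.arange(self.ny) + 0.5) * self.cell_size

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the cells containing map points (x, y).

        Points outside the extent get index -1 in both row and col.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.nx) | (row < 0) | (row >= self.ny)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin[1] + (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def like(self, values: np.ndarray) -> "Grid":
        """A new grid with the same geometry and the given values."""
        return Grid(values, self.cell_size, self.origin, self.nodata)


# Accepted synonym used throughout for DEMs.
ElevationGrid = Grid


def validate_elevation(grid: Grid) -> None:
    """Check DEM invariants: finite values non-negative."""
    vals = grid.values[grid.finite_mask()]
    if vals.size == 0:
        raise ValueError("elevation grid has no finite cells")
    if np.any(vals < 0):
        raise ValueError("elevation below 0 m a.s.l.")


def slope_aspect(dem: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Terrain slope (radians) and downslope aspect (radians, clockwise from north).

    Gradients by central differences on cell centres; aspect of flat cells is 0.
    """
    dz_dy, dz_dx = np.gradient(dem.values, dem.cell_size)
    slope = np.arctan(np.hypot(dz_dx, dz_dy))
    # downslope direction is -grad; azimuth measured from north (y axis), clockwise
    aspect = np.arctan2(-dz_dx, -dz_dy) % (2 * np.pi)
    aspect = np.where(slope > 0, aspect, 0.0)
    return slope, aspect


def write_ascii_grid(path, grid: Grid) -> None:
    """Write an ESRI ASCII grid (.asc). First data row is the northernmost."""
    vals = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
    header = (
        f"ncols {grid.nx}\n"
        f"nrows {grid.ny}\n"
        f"xllcorner {grid.origin[0]!r}\n"
        f"yllcorner {grid.origin[1]!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals[::-1], fmt="%.6f")


def read_ascii_grid(path) -> Grid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    nodata = header.get("nodata_value", NODATA)
    data = np.where(data == nodata, np.nan, data)[::-1]
    return Grid(
        data,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        nodata=nodata,
    )
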