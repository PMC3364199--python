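"""Kernel density surfaces and catch-per-unit-effort (CPUE) indices.

Density surfaces are regular planar grids (0.5-km cells by default) built
from weighted point observations with a quartic (biweight) kernel of fixed
search radius.  A CPUE surface divides an observation density by an effort
density cellwise, masking cells with negligible effort instead of letting
the ratio explode.

Grids follow the Esri ASCII raster convention: row 0 is the northernmost
row, ``xllcorner``/``yllcorner`` give the lower-left corner, and the format
round-trips as plain text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "PointObservations", "DensitySurface", "kernel_density", "cpue_surface"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular analysis grid (planar km)."""

    xmin: float
    ymin: float
    cellsize: float = 0.5
    nrows: int = 1
    ncols: int = 1

    def __post_init__(self) -> None:
        if self.cellsize <= 0 or self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid needs positive cell size and dimensions")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x of each column, y of each row); y is descending (north first)."""
        xs = self.xmin + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.ymin + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return xs, ys

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing a point; raises outside the grid."""
        col = int(np.floor((x - self.xmin) / self.cellsize))
        row_from_bottom = int(np.floor((y - self.ymin) / self.cellsize))
        row = self.nrows - 1 - row_from_bottom
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({x}, {y}) falls outside the grid")
        return row, col


@dataclass
class PointObservations:
    """Weighted point observations (weights >= 0; planar km)."""

    x: np.ndarray
    y: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        self.weight = np.atleast_1d(np.asarray(self.weight, dtype=float))
        if not (self.x.shape == self.y.shape == self.weight.shape):
            raise ValueError("x, y, weight must have equal length")
        if self.x.size and not np.all(np.isfinite(self.x) & np.isfinite(self.y)):
            raise ValueError("coordinates must be finite")
        if np.any(self.weight < 0):
            raise ValueError("weights must be nonnegative")

    def __len__(self) -> int:
        return self.x.size


@dataclass
class DensitySurface:
    """A gridded nonnegative field; ``mask`` marks unsampled cells."""

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError("values shape does not match grid spec")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values")

    def value_at(self, x: float, y: float) -> float:
        """Value of the cell containing (x, y); no interpolation."""
        r, c = self.grid.cell_of(x, y)
        if self.mask is not None and self.mask[r, c]:
            return float("nan")
        return float(self.values[r, c])

    def total(self) -> float:
        """Integral of the surface: cell sum times cell area."""
        return float(np.nansum(self.values) * self.grid.cellsize**2)

    # Esri ASCII grid interchange (plain text, 6-line header)

    def to_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        vals = self.values.copy()
        if self.mask is not None:
            vals[self.mask] = nodata
        header = (
            f"ncols {self.grid.ncols}\n"
            f"nrows {self.grid.nrows}\n"
            f"xllcorner {self.grid.xmin}\n"
            f"yllcorner {self.grid.ymin}\n"
            f"cellsize {self.grid.cellsize}\n"
            f"NODATA_value {nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.10g")

    @classmethod
    def from_ascii(cls, path: str | Path) -> "DensitySurface":
        with open(path) as fh:
            hdr = {}
            for _ in range(6):
                key, val = fh.readline().split()
                hdr[key.lower()] = float(val)
            vals = np.loadtxt(fh, ndmin=2)
        grid = GridSpec(
            xmin=hdr["xllcorner"],
            ymin=hdr["yllcorner"],
            cellsize=hdr["cellsize"],
            nrows=int(hdr["nrows"]),
            ncols=int(hdr["ncols"]),
        )
        nodata = hdr.get("nodata_value")
        mask = None
        if nodata is not None:
            mask = vals == nodata
            vals = np.where(mask, 0.0, vals)
            if not mask.any():
                mask = None
        return cls(grid, vals, mask)


def kernel_density(points: PointObservations, grid: GridSpec, radius: float = 2.0) -> DensitySurface:
    """Quartic-kernel density surface from weighted points.

    Each cell centre receives ``sum_i w_i * K(d_i) / r^2`` with the quartic
    (biweight) kernel ``K(d) = (3/pi) (1 - d^2/r^2)^2`` for ``d < r`` and 0
    beyond — a density per km^2 whose integral over the grid equals the
    total weight, up to truncation at the grid edge.  Defaults mirror a
    2-km search radius on 0.5-km cells.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    values = np.zeros((grid.nrows, grid.ncols))
    if len(points) == 0:
        return DensitySurface(grid, values)
    xs, ys = grid.cell_centers()
    r2 = radius * radius
    norm = 3.0 / (np.pi * r2)
    for px, py, w in zip(points.x, points.y, points.weight):
        if w == 0.0:
            continue
        # restrict to the window of cells the kernel can reach
        c0 = max(0, int(np.floor((px - radius - grid.xmin) / grid.cellsize)) - 1)
        c1 = min(grid.ncols, int(np.ceil((px + radius - grid.xmin) / grid.cellsize)) + 1)
        rows_in = (np.abs(ys - py) <= radius).nonzero()[0]
        if rows_in.size == 0 or c0 >= c1:
            continue
        dx2 = (xs[c0:c1] - px) ** 2
        dy2 = (ys[rows_in] - py) ** 2
        d2 = dy2[:, None] + dx2[None, :]
        u = 1.0 - d2 / r2
        np.maximum(u, 0.0, out=u)
        values[np.ix_(rows_in, range(c0, c1))] += w * norm * u * u
    return DensitySurface(grid, values)


def cpue_surface(
    numerator: DensitySurface,
    effort: DensitySurface,
    effort_floor: float | None = None,
) -> DensitySurface:
    """Cellwise observation density per unit effort density.

    Cells whose effort falls below ``effort_floor`` (default: 1% of the
    maximum effort cell) are masked as unsampled rather than divided.
    """
    if numerator.grid != effort.grid:
        raise ValueError("numerator and effort surfaces are on different grids")
    if effort_floor is None:
        effort_floor = 0.01 * float(effort.values.max())
    if effort_floor <= 0:
        warnings.warn("effort surface is empty; CPUE fully masked", stacklevel=2)
        mask = np.ones_like(numerator.values, dtype=bool)
        return DensitySurface(numerator.grid, np.zeros_like(numerator.values), mask)
    mask = effort.values < effort_floor
    if effort.mask is not None:
        mask |= effort.mask
    if numerator.mask is not None:
        mask |= numerator.mask
    vals = np.where(mask, 0.0, numerator.values / np.maximum(effort.values, effort_floor))
    return DensitySurface(numerator.grid, vals, mask)
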