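"""Landscape covariate rasters and cost surfaces.

Gridded covariates (road density, terrain ruggedness, waterbody density) are
prepared in four steps before entering a non-Euclidean detection model:
block aggregation to the working resolution, linear rescaling to [1, 10] so
that resistance coefficients are comparable across covariates, and an
exponential transform ``cost = exp(alpha2 * z)`` mapping the scaled covariate
to a strictly positive per-cell movement cost.  Zeros are never allowed in a
cost surface because accumulated-cost shortest paths require positive edge
weights.

Grid convention: row 0 is the northernmost row, coordinates are projected
metres, ``(xll, yll)`` is the lower-left corner of the grid, and cell centers
sit at half-cell offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


@dataclass
class CostRaster:
    """A single-band grid of finite reals with geometry metadata.

    Parameters
    ----------
    values : (nrows, ncols) float array
        Cell values, row 0 = northernmost row.  NaN marks nodata.
    cellsize : float
        Cell edge length in metres (> 0).
    xll, yll : float
        Projected coordinates (metres) of the lower-left grid corner.
    meta : dict
        Free-form provenance flags (e.g. ``partial_blocks`` set by
        :func:`aggregate_raster` when the factor did not divide the grid).
    """

    values: np.ndarray
    cellsize: float
    xll: float = 0.0
    yll: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D array")
        if not self.cellsize > 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cellsize,
            self.yll + self.nrows * self.cellsize,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x and y coordinates of every cell center, shaped like ``values``."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.xll + (cols + 0.5) * self.cellsize
        y = self.yll + (self.nrows - rows - 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/column of the cell containing a point.

        Points exactly on an interior cell boundary resolve to the
        lower-indexed cell.
        """
        fx = (x - self.xll) / self.cellsize
        fy = (self.yll + self.nrows * self.cellsize - y) / self.cellsize
        if not (0 <= fx <= self.ncols and 0 <= fy <= self.nrows):
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        col = int(math.floor(fx))
        row = int(math.floor(fy))
        if fx == col and col > 0:
            col -= 1
        if fy == row and row > 0:
            row -= 1
        col = min(col, self.ncols - 1)
        row = min(row, self.nrows - 1)
        return row, col

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        x = self.xll + (col + 0.5) * self.cellsize
        y = self.yll + (self.nrows - row - 0.5) * self.cellsize
        return x, y


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def read_ascii_grid(path) -> CostRaster:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        body = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    values = np.asarray(body, dtype=float).reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return CostRaster(
        values,
        cellsize=header["cellsize"],
        xll=header.get("xllcorner", 0.0),
        yll=header.get("yllcorner", 0.0),
    )


def write_ascii_grid(raster: CostRaster, path, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    vals = np.where(raster.nodata_mask, nodata, raster.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xll:.6f}\n")
        fh.write(f"yllcorner {raster.yll:.6f}\n")
        fh.write(f"cellsize {raster.cellsize:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        np.savetxt(fh, vals, fmt="%.8g")


# ---------------------------------------------------------------------------
# Aggregation / rescaling / transforms
# ---------------------------------------------------------------------------

def aggregate_raster(raster: CostRaster, factor: int, method: str = "mean") -> CostRaster:
    """Coarsen a raster by an integer factor using block sum or mean.

    Each output cell covers a ``factor x factor`` block of input cells;
    nodata cells are ignored within a block (a block of only nodata stays
    nodata).  Partial blocks at the south/east edges aggregate over the
    available cells and set ``meta['partial_blocks']``.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if method not in ("sum", "mean"):
        raise ValueError(f"unknown aggregation method {method!r}")
    if factor > raster.nrows and factor > raster.ncols:
        raise ValueError("aggregation factor exceeds both raster dimensions")
    if factor == 1:
        return replace(raster, values=raster.values.copy(),
                       meta=dict(raster.meta))

    nr, nc = raster.nrows, raster.ncols
    out_r = -(-nr // factor)
    out_c = -(-nc // factor)
    padded = np.full((out_r * factor, out_c * factor), np.nan)
    padded[:nr, :nc] = raster.values
    blocks = padded.reshape(out_r, factor, out_c, factor).swapaxes(1, 2)
    with np.errstate(invalid="ignore"):
        if method == "sum":
            out = np.nansum(blocks, axis=(2, 3))
        else:
            out = np.nanmean(blocks, axis=(2, 3))
    all_nan = np.isnan(blocks).all(axis=(2, 3))
    out = np.where(all_nan, np.nan, out)

    meta = dict(raster.meta)
    if nr % factor or nc % factor:
        meta["partial_blocks"] = True
    # output grid keeps the same upper-left (north-west) anchor
    new_cell = raster.cellsize * factor
    new_yll = raster.yll + nr * raster.cellsize - out_r * new_cell
    return CostRaster(out, cellsize=new_cell, xll=raster.xll, yll=new_yll,
                      meta=meta)


def rescale_to_1_10(raster: CostRaster) -> CostRaster:
    """Linearly rescale non-nodata values onto [1, 10].

    The minimum maps to 1 and the maximum to 10 so that resistance
    coefficients are comparable across covariates; a constant raster maps
    everywhere to 1 (no resistance signal).  The output never contains
    zeros, as required by accumulated-cost path computation.
    """
    vals = raster.values
    finite = ~raster.nodata_mask
    if not finite.any():
        raise ValueError("cannot rescale an all-nodata raster")
    lo = np.nanmin(vals)
    hi = np.nanmax(vals)
    if hi == lo:
        out = np.where(finite, 1.0, np.nan)
    else:
        out = 1.0 + 9.0 * (vals - lo) / (hi - lo)
    return replace(raster, values=out, meta=dict(raster.meta))


def cost_from_covariate(z: CostRaster, alpha2: float) -> CostRaster:
    """Exponential resistance transform ``cost = exp(alpha2 * z)``.

    alpha2 > 0 means the covariate impedes movement (higher covariate,
    higher cost); alpha2 < 0 means it facilitates movement.  Costs are
    strictly positive for any finite alpha2.
    """
    if not np.isfinite(alpha2):
        raise ValueError("alpha2 must be finite")
    return replace(z, values=np.exp(alpha2 * z.values), meta=dict(z.meta))


# ---------------------------------------------------------------------------
# Vector Ruggedness Measure
# ---------------------------------------------------------------------------

def vrm(dem: CostRaster, neighborhood: int = 3) -> CostRaster:
    """Vector Ruggedness Measure from a DEM.

    Per-cell slope and aspect (Horn 3x3 finite differences) define a unit
    surface-normal vector; VRM is one minus the length of the mean normal
    over a ``neighborhood x neighborhood`` window.  Flat and uniformly
    tilted terrain give 0; values approach 1 only for extremely broken
    terrain.  Adding a constant to the DEM leaves VRM unchanged.
    """
    if neighborhood < 3 or neighborhood % 2 == 0:
        raise ValueError("neighborhood must be an odd integer >= 3")
    z = dem.values
    if np.isnan(z).any():
        raise ValueError("VRM requires a complete (no-nodata) DEM")

    # odd reflection preserves linear trends, so planes stay planes at edges
    zp = np.pad(z, 1, mode="reflect", reflect_type="odd")
    cs = dem.cellsize
    # Horn's method: 3x3 weighted differences
    dzdx = (
        (zp[:-2, 2:] + 2 * zp[1:-1, 2:] + zp[2:, 2:])
        - (zp[:-2, :-2] + 2 * zp[1:-1, :-2] + zp[2:, :-2])
    ) / (8.0 * cs)
    dzdy = (
        (zp[:-2, :-2] + 2 * zp[:-2, 1:-1] + zp[:-2, 2:])
        - (zp[2:, :-2] + 2 * zp[2:, 1:-1] + zp[2:, 2:])
    ) / (8.0 * cs)

    slope = np.arctan(np.hypot(dzdx, dzdy))
    aspect = np.arctan2(dzdy, -dzdx)
    xy = np.sin(slope)
    nx = xy * np.cos(aspect)
    ny = xy * np.sin(aspect)
    nz = np.cos(slope)

    size = neighborhood
    mx = ndimage.uniform_filter(nx, size=size, mode="nearest")
    my = ndimage.uniform_filter(ny, size=size, mode="nearest")
    mz = ndimage.uniform_filter(nz, size=size, mode="nearest")
    resultant = np.sqrt(mx**2 + my**2 + mz**2)
    out = np.clip(1.0 - resultant, 0.0, 1.0)
    return replace(dem, values=out, meta=dict(dem.meta))
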