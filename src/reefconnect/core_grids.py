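"""Grid geometry, masks, reef density, and raster I/O.

The geometric backbone shared by every stage of the pipeline: a regular
Cartesian bathymetry raster (metres, x east / y north, cell-centre
registration, origin at the lower-left corner, 0-based indices) plus
boolean land / reef / region masks on the same raster.

Rasters are exchanged either as ESRI ASCII grids (plain text, the
``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value`` dialect) or as
NetCDF files with ``depth(y, x)`` and ``land_mask(y, x)`` variables.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import xarray as xr

logger = logging.getLogger(__name__)

#: Default cell size, metres.
DEFAULT_DX = 500.0
#: Depth cap representing the surface mixed layer, metres.
DEFAULT_DEPTH_CAP = 80.0
#: Depth below Low Water Datum under which a cell counts as reef, metres.
REEF_DEPTH_THRESHOLD = 5.0

_ASCII_NODATA = -9999.0


class GridFormatError(ValueError):
    """Raised for malformed or unsupported raster files."""


@dataclass
class BathymetryGrid:
    """Depth raster with land mask.

    Parameters
    ----------
    depth
        Water depth in metres, positive down, shape ``(n_y, n_x)`` with
        row 0 the southernmost row.  NaN under land cells.
    land_mask
        Boolean, True where the cell is land.
    dx
        Cell size in metres (square cells).
    origin
        ``(x0, y0)`` of the lower-left cell *corner*, metres.
    """

    depth: np.ndarray
    land_mask: np.ndarray
    dx: float = DEFAULT_DX
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if self.depth.shape != self.land_mask.shape:
            raise ValueError("depth and land_mask shapes differ")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        water = ~self.land_mask
        if np.any(~np.isfinite(self.depth[water])):
            raise ValueError("depth must be finite on water cells")
        if np.any(self.depth[water] < 0):
            raise ValueError("depth must be >= 0 on water cells")

    @property
    def n_y(self) -> int:
        return self.depth.shape[0]

    @property
    def n_x(self) -> int:
        return self.depth.shape[1]

    @property
    def water_mask(self) -> np.ndarray:
        return ~self.land_mask

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of cell-centre x and y coordinates, metres."""
        x0, y0 = self.origin
        x = x0 + (np.arange(self.n_x) + 0.5) * self.dx
        y = y0 + (np.arange(self.n_y) + 0.5) * self.dx
        return x, y

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Column/row indices of the cells containing points (x, y)."""
        x0, y0 = self.origin
        ix = np.floor((np.asarray(x) - x0) / self.dx).astype(int)
        iy = np.floor((np.asarray(y) - y0) / self.dx).astype(int)
        return ix, iy


@dataclass
class RegionMask:
    """A named boolean cell mask on a grid (lagoon, far field, ...)."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


def reef_mask(grid: BathymetryGrid, threshold: float = REEF_DEPTH_THRESHOLD) -> np.ndarray:
    """Boolean mask of reef cells: water shallower than *threshold* m LWD.

    Reef cells are always a subset of water cells.
    """
    with np.errstate(invalid="ignore"):
        shallow = grid.depth < threshold
    return shallow & grid.water_mask


def reef_density(
    grid: BathymetryGrid,
    region: RegionMask | np.ndarray | None = None,
    threshold: float = REEF_DEPTH_THRESHOLD,
    include_land: bool = True,
) -> float:
    """Fraction of cells in *region* that are reef (depth < *threshold*).

    Reef density is a bathymetric quantity — the fraction of map area
    covered by reef flat — distinct from coral cover (live coral fraction
    of the reef substrate).  By default the denominator counts every cell
    of the region, land included; pass ``include_land=False`` to count
    water cells only.
    """
    if region is None:
        sel = np.ones_like(grid.land_mask, dtype=bool)
    else:
        sel = region.mask if isinstance(region, RegionMask) else np.asarray(region, bool)
    if sel.shape != grid.depth.shape:
        raise ValueError("region mask shape does not match grid")
    if not np.any(sel & grid.water_mask):
        raise ValueError("region contains no water cells")
    denom = sel if include_land else (sel & grid.water_mask)
    n_denom = int(denom.sum())
    n_reef = int((reef_mask(grid, threshold) & sel).sum())
    return n_reef / n_denom


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

_ASCII_HEADER_FIELDS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _read_ascii(path: str, depth_cap: float) -> BathymetryGrid:
    with open(path) as fh:
        header: dict[str, float] = {}
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise GridFormatError("empty raster file")
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _ASCII_HEADER_FIELDS + ("nodata_value",):
                try:
                    header[parts[0].lower()] = float(parts[1])
                except ValueError:
                    raise GridFormatError(
                        f"malformed header field {parts[0]!r}: {parts[1]!r}"
                    ) from None
            else:
                fh.seek(pos)
                break
        for name in _ASCII_HEADER_FIELDS:
            if name not in header:
                raise GridFormatError(f"missing header field {name!r}")
        ncols = int(header["ncols"])
        nrows = int(header["nrows"])
        if ncols <= 0 or nrows <= 0:
            raise GridFormatError("ncols/nrows must be positive")
        nodata = header.get("nodata_value", _ASCII_NODATA)
        data = np.loadtxt(fh, dtype=float)
    data = np.atleast_2d(data)
    if data.shape != (nrows, ncols):
        raise GridFormatError(
            f"data shape {data.shape} does not match header ({nrows}, {ncols})"
        )
    depth = np.flipud(data).copy()  # file rows run north->south
    land = depth == nodata
    depth[land] = np.nan
    return _finalize(depth, land, header["cellsize"],
                     (header["xllcorner"], header["yllcorner"]), depth_cap)


def _read_netcdf(path: str, depth_cap: float) -> BathymetryGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        if "depth" not in ds:
            raise GridFormatError("missing variable 'depth'")
        depth = np.asarray(ds["depth"].values, dtype=float)
        if depth.ndim != 2:
            raise GridFormatError("depth must be 2-D (y, x)")
        if "land_mask" in ds:
            land = np.asarray(ds["land_mask"].values).astype(bool)
        else:
            land = ~np.isfinite(depth)
        nodata = ds["depth"].attrs.get("nodata")
        if nodata is not None:
            land |= depth == nodata
        x = np.asarray(ds["x"].values, dtype=float)
        y = np.asarray(ds["y"].values, dtype=float)
    steps = np.concatenate([np.diff(x), np.diff(y)])
    if steps.size == 0:
        raise GridFormatError("grid must have at least 2 cells per axis")
    dx = float(steps[0])
    if not np.allclose(steps, dx, rtol=1e-6, atol=1e-6):
        raise GridFormatError("non-uniform cell size is unsupported")
    depth = depth.copy()
    depth[land] = np.nan
    origin = (float(x[0]) - dx / 2, float(y[0]) - dx / 2)
    return _finalize(depth, land, dx, origin, depth_cap)


def _finalize(depth, land, dx, origin, depth_cap) -> BathymetryGrid:
    if np.all(land):
        logger.warning("raster contains no water cells (all nodata)")
    if depth_cap is not None:
        water = ~land
        depth[water] = np.minimum(depth[water], depth_cap)
    return BathymetryGrid(depth=depth, land_mask=land, dx=float(dx), origin=origin)


def read_grid(path: str, depth_cap: float | None = DEFAULT_DEPTH_CAP) -> BathymetryGrid:
    """Read a bathymetry raster (ESRI ASCII ``.asc``/``.txt`` or NetCDF ``.nc``).

    Nodata cells become land; depth is capped at *depth_cap* (the mixed-layer
    maximum; ``None`` disables capping).
    """
    ext = os.path.splitext(path)[1].lower()
    if ext == ".nc":
        return _read_netcdf(path, depth_cap)
    return _read_ascii(path, depth_cap)


def write_grid(grid: BathymetryGrid, path: str) -> None:
    """Write *grid* to ESRI ASCII or NetCDF, chosen by extension.

    ``read_grid(write_grid(g))`` reproduces depth and land mask exactly
    (provided depths already respect the read-time cap).
    """
    ext = os.path.splitext(path)[1].lower()
    if ext == ".nc":
        x, y = grid.cell_centres()
        ds = xr.Dataset(
            {
                "depth": (("y", "x"), np.where(grid.land_mask, np.nan, grid.depth)),
                "land_mask": (("y", "x"), grid.land_mask.astype(np.int8)),
            },
            coords={"x": x, "y": y},
        )
        ds["depth"].attrs["units"] = "m"
        ds.to_netcdf(path, engine="scipy")
        return
    data = np.where(grid.land_mask, _ASCII_NODATA, grid.depth)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_x}\n")
        fh.write(f"nrows {grid.n_y}\n")
        fh.write(f"xllcorner {float(grid.origin[0])!r}\n")
        fh.write(f"yllcorner {float(grid.origin[1])!r}\n")
        fh.write(f"cellsize {float(grid.dx)!r}\n")
        fh.write(f"NODATA_value {_ASCII_NODATA!r}\n")
        for row in np.flipud(data):
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def write_mask(mask: np.ndarray, grid: BathymetryGrid, path: str) -> None:
    """Write a boolean mask as a companion 0/1 ESRI ASCII raster."""
    mg = BathymetryGrid(
        depth=np.asarray(mask, float),
        land_mask=np.zeros_like(grid.land_mask),
        dx=grid.dx,
        origin=grid.origin,
    )
    write_grid(mg, path)


def read_mask(path: str) -> np.ndarray:
    """Read a 0/1 companion raster back as a boolean mask."""
    g = read_grid(path, depth_cap=None)
    vals = np.where(g.land_mask, 0.0, g.depth)
    return vals != 0
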