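"""Lightweight georeferenced rasters on regular WGS84 lat/lon grids.

Two on-disk formats are supported, both self-contained:

* ESRI ASCII grid (``.asc``) — plain text, the exchange format most GIS
  tools read and write.
* TIFF with an ESRI world file sidecar (``.tif`` + ``.tfw``) via
  :mod:`tifffile`.

A raster is north-up with square-ish cells described by the cell size in
degrees and the coordinates of the grid's west and north edges (cell-edge
registration). No-data cells are NaN in memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_raster", "write_raster", "haversine_km", "EARTH_RADIUS_KM"]

EARTH_RADIUS_KM = 6371.0


@dataclass
class Raster:
    """A 2-D grid of values in WGS84 geographic coordinates.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values, row 0 at the northern edge. No-data cells are NaN.
    west, north : float
        Longitude of the west edge and latitude of the north edge, degrees.
    cellsize : float
        Cell side length in degrees (same in both axes).
    """

    values: np.ndarray
    west: float
    north: float
    cellsize: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def south(self) -> float:
        return self.north - self.shape[0] * self.cellsize

    @property
    def east(self) -> float:
        return self.west + self.shape[1] * self.cellsize

    def cell_index(self, lat: float, lon: float) -> tuple[int, int]:
        """Row/column of the cell containing a point; raises if outside."""
        row = int(math.floor((self.north - lat) / self.cellsize))
        col = int(math.floor((lon - self.west) / self.cellsize))
        nrows, ncols = self.shape
        # points exactly on the south/east edge belong to the last cell
        if lat == self.south:
            row = nrows - 1
        if lon == self.east:
            col = ncols - 1
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise ValueError(f"point ({lat}, {lon}) outside raster extent")
        return row, col

    def sample(self, lats, lons) -> np.ndarray:
        """Value of the cell containing each point (no interpolation).

        Points outside the extent yield NaN, like no-data cells.
        """
        lats = np.atleast_1d(np.asarray(lats, dtype=float))
        lons = np.atleast_1d(np.asarray(lons, dtype=float))
        out = np.full(lats.shape, np.nan)
        for i, (la, lo) in enumerate(zip(lats, lons)):
            try:
                r, c = self.cell_index(la, lo)
            except ValueError:
                continue
            out[i] = self.values[r, c]
        return out

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lats, lons) 1-D arrays of cell-center coordinates."""
        nrows, ncols = self.shape
        lats = self.north - (np.arange(nrows) + 0.5) * self.cellsize
        lons = self.west + (np.arange(ncols) + 0.5) * self.cellsize
        return lats, lons


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points in degrees (broadcasting)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


_ASC_NODATA = -9999.0


def write_raster(raster: Raster, path: str | Path) -> None:
    """Write a raster as ``.asc`` (ESRI ASCII grid) or ``.tif`` + ``.tfw``."""
    path = Path(path)
    if path.suffix == ".asc":
        vals = np.where(np.isnan(raster.values), _ASC_NODATA, raster.values)
        nrows, ncols = raster.shape
        header = (
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {raster.west!r}\nyllcorner {raster.south!r}\n"
            f"cellsize {raster.cellsize!r}\nNODATA_value {_ASC_NODATA}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.10g")
    elif path.suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, raster.values.astype(np.float32))
        cs = raster.cellsize
        # world file: x-scale, rotations, y-scale, x/y of the CENTER of the
        # upper-left cell
        tfw = path.with_suffix(".tfw")
        tfw.write_text(
            f"{cs!r}\n0.0\n0.0\n{-cs!r}\n{raster.west + cs / 2!r}\n{raster.north - cs / 2!r}\n"
        )
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r} (use .asc or .tif)")


def read_raster(path: str | Path) -> Raster:
    """Read an ``.asc`` grid or a ``.tif`` with a ``.tfw`` world file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster layer not found: {path}")
    if path.suffix == ".asc":
        header: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            for _ in range(6):
                pos = fh.tell()
                parts = fh.readline().split()
                if len(parts) != 2 or not _is_number(parts[1]):
                    break
                header[parts[0].lower()] = float(parts[1])
            fh.seek(pos if len(header) < 6 else fh.tell())
            fh.seek(0)
            values = np.loadtxt(fh, skiprows=len(header))
        values = np.atleast_2d(values)
        nodata = header.get("nodata_value", _ASC_NODATA)
        values = np.where(values == nodata, np.nan, values)
        cellsize = header["cellsize"]
        north = header["yllcorner"] + header["nrows"] * cellsize
        return Raster(values, west=header["xllcorner"], north=north, cellsize=cellsize)
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        values = tifffile.imread(path).astype(float)
        tfw = path.with_suffix(".tfw")
        if not tfw.exists():
            raise FileNotFoundError(f"world file missing for {path}: {tfw}")
        a, _, _, d, cx, cy = (float(x) for x in tfw.read_text().split())
        cs = abs(a)
        if not math.isclose(cs, abs(d), rel_tol=1e-9):
            raise ValueError("anisotropic cells are not supported")
        return Raster(values, west=cx - cs / 2, north=cy + cs / 2, cellsize=cs)
    raise ValueError(f"unsupported raster format: {path.suffix!r} (use .asc or .tif)")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
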