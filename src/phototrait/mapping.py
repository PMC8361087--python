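"""Gridded global trait maps from geolocated point predictions.

Normalized model outputs are inverted to original trait units
(``10^(norm·(max−min)+min)``), deduplicated against the training data, and
interpolated with inverse-distance weighting onto a regular WGS84 grid
(default 0°30′). Cells farther than a buffer (default 100 km, great-circle)
from every observation, or off a land mask, are masked out. A quantile-range
map (q.9 − q.1) accompanies the mean map as an uncertainty reference;
latitudinal profiles and raster-to-raster Pearson comparison support
plausibility checks against published trait map products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import RegularGridInterpolator

from .datasets import NormalizationParams
from .rasters import Raster, haversine_km

__all__ = [
    "PointPrediction",
    "TraitGrid",
    "invert_targets",
    "deduplicate_against_training",
    "idw_grid",
    "quantile_range_grid",
    "latitudinal_profile",
    "resample_bilinear",
    "compare_grids",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PointPrediction:
    """One georeferenced trait prediction in original units."""

    record_id: str
    lat: float
    lon: float
    value: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0):
            raise ValueError(f"coordinates out of bounds for {self.record_id!r}")
        if not self.value > 0:
            raise ValueError(f"trait value must be positive for {self.record_id!r}")


@dataclass
class TraitGrid:
    """A georeferenced grid of aggregated trait values with a validity mask."""

    values: np.ndarray
    mask: np.ndarray
    resolution: float
    west: float = -180.0
    north: float = 90.0
    trait_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("values must be finite wherever mask is true")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nrows, ncols = self.values.shape
        lats = self.north - (np.arange(nrows) + 0.5) * self.resolution
        lons = self.west + (np.arange(ncols) + 0.5) * self.resolution
        return lats, lons

    def to_raster(self) -> Raster:
        vals = np.where(self.mask, self.values, np.nan)
        return Raster(vals, west=self.west, north=self.north, cellsize=self.resolution)

    @classmethod
    def from_raster(cls, raster: Raster, trait_id: str | None = None) -> "TraitGrid":
        mask = np.isfinite(raster.values)
        return cls(
            values=np.where(mask, raster.values, 0.0),
            mask=mask,
            resolution=raster.cellsize,
            west=raster.west,
            north=raster.north,
            trait_id=trait_id,
        )

    def plot(self, ax=None, log10: bool = False, **imshow_kw):
        """Render the grid with matplotlib; ``log10`` affects display only."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        shown = np.where(self.mask, self.values, np.nan)
        if log10:
            shown = np.log10(shown)
        extent = (self.west, self.west + self.values.shape[1] * self.resolution,
                  self.north - self.values.shape[0] * self.resolution, self.north)
        im = ax.imshow(shown, extent=extent, origin="upper", **imshow_kw)
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
        return im


def invert_targets(norm_predictions, p: NormalizationParams) -> np.ndarray:
    """Undo min–max scaling and the log10 transform: ``10^(y·range + min)``."""
    y = np.asarray(norm_predictions, dtype=float)
    return 10.0 ** (y * p.range + p.min_train)


def deduplicate_against_training(
    points: Sequence[PointPrediction], training_ids
) -> list[PointPrediction]:
    """Drop points whose record_id occurs in the training/validation data."""
    blocked = set(training_ids)
    kept = [pt for pt in points if pt.record_id not in blocked]
    if len(kept) < len(points):
        logger.info("removed %d point(s) overlapping the training data", len(points) - len(kept))
    return kept


def _grid_frame(
    resolution_deg: float, bounds: tuple[float, float, float, float]
) -> tuple[np.ndarray, np.ndarray, float, float]:
    west, south, east, north = bounds
    ncols = int(round((east - west) / resolution_deg))
    nrows = int(round((north - south) / resolution_deg))
    if ncols < 1 or nrows < 1:
        raise ValueError("bounds smaller than one cell")
    lats = north - (np.arange(nrows) + 0.5) * resolution_deg
    lons = west + (np.arange(ncols) + 0.5) * resolution_deg
    return lats, lons, west, north


def idw_grid(
    points: Sequence[PointPrediction],
    resolution_deg: float = 0.5,
    power: float = 2.0,
    buffer_km: float = 100.0,
    land_mask: Raster | None = None,
    bounds: tuple[float, float, float, float] = (-180.0, -90.0, 180.0, 90.0),
    exact_eps_km: float = 1e-6,
    trait_id: str | None = None,
) -> TraitGrid:
    """Inverse-distance-weighted interpolation of point values at cell centers.

    Each unmasked cell center receives ``Σ wᵢvᵢ / Σ wᵢ`` with
    ``wᵢ = dᵢ^(−power)`` and ``dᵢ`` the great-circle (haversine) distance to
    point i; a center within ``exact_eps_km`` of one or more points takes
    their mean value exactly. Cells whose nearest point exceeds
    ``buffer_km``, or that fall on a no-data/zero cell of ``land_mask``,
    are masked. ``bounds`` is (west, south, east, north).
    """
    points = list(points)
    if not points:
        raise ValueError("idw_grid requires at least one point")
    if power <= 0 or buffer_km <= 0 or resolution_deg <= 0:
        raise ValueError("power, buffer_km and resolution_deg must be positive")
    lats, lons, west, north = _grid_frame(resolution_deg, bounds)
    plat = np.array([p.lat for p in points])
    plon = np.array([p.lon for p in points])
    pval = np.array([p.value for p in points])

    values = np.zeros((lats.size, lons.size))
    mask = np.zeros((lats.size, lons.size), dtype=bool)
    lon_grid = np.broadcast_to(lons, (plat.size, lons.size))
    for i, lat in enumerate(lats):
        # distances from every point to all cell centers in this row
        d = haversine_km(plat[:, None], plon[:, None], lat, lon_grid)  # (npts, ncols)
        nearest = d.min(axis=0)
        row_valid = nearest <= buffer_km
        if not row_valid.any():
            continue
        exact = d <= exact_eps_km
        with np.errstate(divide="ignore"):
            w = d ** (-power)
        est = np.empty(lons.size)
        hit_cols = exact.any(axis=0)
        if hit_cols.any():
            # exact-hit rule: co-located points are averaged
            sums = (exact * pval[:, None]).sum(axis=0)
            est[hit_cols] = sums[hit_cols] / exact.sum(axis=0)[hit_cols]
        free = ~hit_cols
        if free.any():
            est[free] = (w[:, free] * pval[:, None]).sum(axis=0) / w[:, free].sum(axis=0)
        values[i, row_valid] = est[row_valid]
        mask[i, row_valid] = True

    grid = TraitGrid(values, mask, resolution_deg, west=west, north=north, trait_id=trait_id)
    if land_mask is not None:
        glats, glons = grid.cell_centers()
        lon2, lat2 = np.meshgrid(glons, glats)
        land = land_mask.sample(lat2.ravel(), lon2.ravel()).reshape(grid.values.shape)
        grid.mask &= np.isfinite(land) & (land > 0)
    grid.values[~grid.mask] = 0.0
    return grid


def quantile_range_grid(
    points: Sequence[PointPrediction],
    resolution_deg: float = 0.5,
    q_hi: float = 0.9,
    q_lo: float = 0.1,
    bounds: tuple[float, float, float, float] = (-180.0, -90.0, 180.0, 90.0),
    trait_id: str | None = None,
) -> TraitGrid:
    """Per-cell difference of the ``q_hi`` and ``q_lo`` quantiles of point values.

    Quantiles use linear interpolation between order statistics; a cell with
    a single contributing point, or identical values, maps to 0. Cells with
    no points are masked.
    """
    points = list(points)
    if not points:
        raise ValueError("quantile_range_grid requires at least one point")
    if not 0 <= q_lo < q_hi <= 1:
        raise ValueError("require 0 <= q_lo < q_hi <= 1")
    lats, lons, west, north = _grid_frame(resolution_deg, bounds)
    nrows, ncols = lats.size, lons.size
    cells: dict[tuple[int, int], list[float]] = {}
    for p in points:
        row = min(int((north - p.lat) / resolution_deg), nrows - 1)
        col = min(int((p.lon - west) / resolution_deg), ncols - 1)
        if 0 <= row < nrows and 0 <= col < ncols:
            cells.setdefault((row, col), []).append(p.value)
    values = np.zeros((nrows, ncols))
    mask = np.zeros((nrows, ncols), dtype=bool)
    for (row, col), vals in cells.items():
        arr = np.asarray(vals)
        values[row, col] = float(np.quantile(arr, q_hi) - np.quantile(arr, q_lo))
        mask[row, col] = True
    return TraitGrid(values, mask, resolution_deg, west=west, north=north, trait_id=trait_id)


def latitudinal_profile(grid: TraitGrid, band_deg: float = 5.0) -> pd.DataFrame:
    """Unweighted mean of unmasked cell values per latitude band.

    Bands are [k·band_deg, (k+1)·band_deg); the reported ``lat_band`` is the
    band center. Empty bands are omitted.
    """
    if band_deg <= 0:
        raise ValueError("band_deg must be positive")
    if not grid.mask.any():
        raise ValueError("grid has no unmasked cells")
    lats, _ = grid.cell_centers()
    rows, cols = np.nonzero(grid.mask)
    cell_lats = lats[rows]
    band_idx = np.floor(cell_lats / band_deg).astype(int)
    df = pd.DataFrame({"band": band_idx, "value": grid.values[rows, cols]})
    prof = df.groupby("band")["value"].mean().reset_index()
    prof["lat_band"] = (prof["band"] + 0.5) * band_deg
    return prof[["lat_band", "value"]].sort_values("lat_band", ignore_index=True)


def resample_bilinear(src: TraitGrid, template: TraitGrid) -> TraitGrid:
    """Bilinearly resample ``src`` onto ``template``'s grid (masks propagate)."""
    slats, slons = src.cell_centers()
    svals = np.where(src.mask, src.values, np.nan)
    interp = RegularGridInterpolator(
        (slats[::-1], slons), svals[::-1, :], method="linear", bounds_error=False, fill_value=np.nan
    )
    tlats, tlons = template.cell_centers()
    lon2, lat2 = np.meshgrid(tlons, tlats)
    out = interp(np.column_stack([lat2.ravel(), lon2.ravel()])).reshape(template.values.shape)
    mask = np.isfinite(out)
    return TraitGrid(
        np.where(mask, out, 0.0), mask, template.resolution,
        west=template.west, north=template.north, trait_id=src.trait_id,
    )


def compare_grids(a: TraitGrid, b: TraitGrid) -> tuple[float, float, int]:
    """Pearson r, two-sided p-value and cell count over the joint valid mask.

    ``b`` is first resampled bilinearly onto ``a``'s grid if the geometries
    differ.
    """
    if (b.values.shape != a.values.shape or b.resolution != a.resolution
            or b.west != a.west or b.north != a.north):
        b = resample_bilinear(b, a)
    joint = a.mask & b.mask
    n = int(joint.sum())
    if n < 3:
        raise ValueError("need at least 3 jointly unmasked cells")
    res = stats.pearsonr(a.values[joint], b.values[joint])
    return float(res.statistic), float(res.pvalue), n
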