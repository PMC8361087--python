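"""Fully synthetic test corpora with the statistical structure the pipeline assumes.

The generator emits the four inputs the real pipeline consumes — a trait
table, an occurrence table, RGB images and climate rasters — from a known
generative law, so that every stage (ingestion, linkage, training, mapping)
can be exercised and checked against ground truth without any download.

Each species has a characteristic leaf-disc area fraction and greenness;
each image renders elliptical "leaves" on a textured background with a
per-image jitter of those features. The latent trait of an image is

    trait = base + c_area·a + c_green·g + c_climate·clim + noise,

with ``a`` the analytic disc-area fraction, ``g`` the foreground greenness
and ``clim`` the normalized synthetic annual-mean-temperature at the
image's location. The trait table contains per-species values consistent
with the per-species latent traits, so the species means the ingest module
computes are (noisy) functions of what is visible in the images — the
hypothesis the image models are supposed to exploit, made literally true.

Geolocations fall on a toy rectangular landmass; climate rasters are smooth
latitude/longitude gradients with no-data over the ocean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .rasters import Raster, write_raster

__all__ = ["SyntheticSpec", "SyntheticCorpus", "generate_corpus", "climate_surface", "LAND_BOUNDS"]

logger = logging.getLogger(__name__)

#: (west, south, east, north) of the toy landmass
LAND_BOUNDS = (-150.0, -60.0, 150.0, 70.0)


@dataclass
class SyntheticSpec:
    """Generation parameters; defaults give an informative, mildly noisy corpus."""

    n_species: int = 40
    images_per_species: tuple[int, int] = (2, 8)
    image_size: int = 64
    n_discs: int = 3
    trait_base: float = 0.5
    c_area: float = 2.0
    c_green: float = 0.5
    c_climate: float = 0.0
    sigma_noise: float = 0.02
    sd_frac: float = 0.15
    trait_records_per_species: int = 4
    range_radius_deg: float = 5.0
    trait_id: str = "LA"
    climate_cellsize_deg: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.images_per_species[0] < 1:
            raise ValueError("counts must be >= 1")
        if self.images_per_species[0] > self.images_per_species[1]:
            raise ValueError("images_per_species must be a (min, max) range")
        if self.sigma_noise < 0 or self.sd_frac < 0:
            raise ValueError("noise levels must be non-negative")
        worst = self.trait_base + min(self.c_area, 0) + min(self.c_green, 0) + min(
            self.c_climate, 0
        ) - 4 * self.sigma_noise
        if worst <= 0:
            raise ValueError(
                "parameter combination can yield non-positive trait values; "
                "raise trait_base or reduce negative coefficients/noise"
            )


@dataclass
class SyntheticCorpus:
    """In-memory handle to a generated corpus plus the paths written."""

    out_dir: Path
    trait_csv: Path
    occurrence_csv: Path
    image_dir: Path
    climate_dir: Path
    ground_truth: pd.DataFrame
    images: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def climate_surface(name: str, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Smooth synthetic bioclim surfaces (vectorized over lat/lon in degrees)."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    coslat = np.cos(np.radians(lat))
    if name == "bio1":  # annual mean temperature, °C
        return 28.0 - 0.45 * np.abs(lat) + 2.0 * np.sin(np.radians(lon))
    if name == "bio4":  # temperature seasonality
        return 150.0 + 900.0 * np.abs(lat) / 90.0
    if name == "bio7":  # temperature annual range, °C
        return 12.0 + 0.35 * np.abs(lat)
    if name == "bio12":  # annual precipitation, mm
        return 200.0 + 2400.0 * coslat**2
    if name == "bio13":
        return 0.25 * climate_surface("bio12", lat, lon)
    if name == "bio14":
        return 0.05 * climate_surface("bio12", lat, lon)
    if name == "bio15":  # precipitation seasonality
        return 40.0 + 30.0 * np.sin(np.radians(2.0 * np.abs(lat)))
    raise ValueError(f"unknown climate surface {name!r}")


def _climate_rasters(spec: SyntheticSpec) -> dict[str, Raster]:
    cs = spec.climate_cellsize_deg
    nrows = int(round(180.0 / cs))
    ncols = int(round(360.0 / cs))
    lats = 90.0 - (np.arange(nrows) + 0.5) * cs
    lons = -180.0 + (np.arange(ncols) + 0.5) * cs
    lon2, lat2 = np.meshgrid(lons, lats)
    west, south, east, north = LAND_BOUNDS
    ocean = ~((lat2 >= south) & (lat2 <= north) & (lon2 >= west) & (lon2 <= east))
    out = {}
    for name in ("bio1", "bio4", "bio7", "bio12", "bio13", "bio14", "bio15"):
        vals = climate_surface(name, lat2, lon2)
        vals = np.where(ocean, np.nan, vals)
        out[name] = Raster(vals, west=-180.0, north=90.0, cellsize=cs)
    return out


def _clim_norm_range() -> tuple[float, float]:
    """Extrema of the bio1 surface over the landmass (analytic)."""
    west, south, east, north = LAND_BOUNDS
    lats = np.linspace(south, north, 400)
    lons = np.linspace(west, east, 400)
    lon2, lat2 = np.meshgrid(lons, lats)
    vals = climate_surface("bio1", lat2, lon2)
    return float(vals.min()), float(vals.max())


def _render_image(
    size: int, a_frac: float, greenness: float, n_discs: int, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Draw ellipses of total analytic area fraction ``a_frac``.

    Placement tries to keep discs disjoint and fully inside the frame;
    overlap is tolerated as a fallback so no area silently disappears. The
    returned fraction is the exact painted pixel fraction (the union mask),
    which for a single non-overlapping disc matches the analytic ellipse
    area π·r₁·r₂ up to rasterization error.
    """
    img = np.empty((size, size, 3))
    base = np.array([0.36, 0.30, 0.22])
    img[:] = base + rng.uniform(-0.08, 0.08, size=(size, size, 3))
    yy, xx = np.mgrid[0:size, 0:size] + 0.5
    per_disc = a_frac * size * size / n_discs
    placed: list[tuple[float, float, float]] = []  # (cx, cy, bounding radius)
    fg = np.zeros((size, size), dtype=bool)
    for _ in range(n_discs):
        best = None
        for _try in range(60):
            ratio = rng.uniform(0.6, 1.6)
            r1 = np.sqrt(per_disc * ratio / np.pi)
            r2 = per_disc / (np.pi * r1)
            rb = max(r1, r2)
            if 2 * rb >= size - 2:
                continue
            cx = rng.uniform(rb + 1, size - rb - 1)
            cy = rng.uniform(rb + 1, size - rb - 1)
            best = (cx, cy, r1, r2, rb)
            if all((cx - px) ** 2 + (cy - py) ** 2 > (rb + pr) ** 2 for px, py, pr in placed):
                break
        if best is None:  # disc larger than the frame: shrink to fit
            rb = (size - 4) / 2.0
            best = (size / 2.0, size / 2.0, rb, rb, rb)
        cx, cy, r1, r2, rb = best
        inside = ((xx - cx) / r1) ** 2 + ((yy - cy) / r2) ** 2 <= 1.0
        color = np.array([0.15, greenness, 0.10])
        img[inside] = color + rng.uniform(-0.03, 0.03, size=(int(inside.sum()), 3))
        placed.append((cx, cy, rb))
        fg |= inside
    return np.clip(img, 0.0, 1.0), float(fg.mean())


def generate_corpus(spec: SyntheticSpec, out_dir: str | Path) -> SyntheticCorpus:
    """Write a complete synthetic corpus under ``out_dir``.

    Outputs: ``traits.csv`` (species, trait_id, value), ``occurrences.csv``
    (record_id, species, image_ref, lat, lon, coord_uncertainty_km), one PNG
    per record under ``images/``, the seven ``bio*.asc`` climate layers
    under ``climate/`` and ``ground_truth.csv`` with the per-image latent
    features and trait values. The same spec and seed reproduce the corpus
    byte for byte.
    """
    out_dir = Path(out_dir)
    image_dir = out_dir / "images"
    climate_dir = out_dir / "climate"
    image_dir.mkdir(parents=True, exist_ok=True)
    climate_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    rasters = _climate_rasters(spec)
    for name, raster in rasters.items():
        write_raster(raster, climate_dir / f"{name}.asc")
    clim_lo, clim_hi = _clim_norm_range()

    west, south, east, north = LAND_BOUNDS
    rows_gt, rows_occ, rows_trait = [], [], []
    images: dict[str, np.ndarray] = {}
    rec = 0
    for s in range(spec.n_species):
        species = f"Plantus species{s:04d}"
        a_sp = rng.uniform(0.08, 0.45)
        g_sp = rng.uniform(0.30, 0.90)
        # each species occupies a climatic niche: a home range of
        # range_radius_deg around a random center, not the whole landmass
        rr = spec.range_radius_deg
        lat_sp = float(rng.uniform(south + rr, north - rr))
        lon_sp = float(rng.uniform(west + rr, east - rr))
        n_img = int(rng.integers(spec.images_per_species[0], spec.images_per_species[1] + 1))
        latents = []
        for _ in range(n_img):
            rid = f"obs{rec:06d}"
            rec += 1
            a_requested = float(np.clip(a_sp * (1.0 + rng.uniform(-0.10, 0.10)), 0.02, 0.55))
            g = float(np.clip(g_sp + rng.uniform(-0.05, 0.05), 0.05, 1.0))
            lat = float(np.clip(lat_sp + rng.uniform(-rr, rr), south, north))
            lon = float(np.clip(lon_sp + rng.uniform(-rr, rr), west, east))
            clim_raw = float(rasters["bio1"].sample(lat, lon)[0])
            clim = (clim_raw - clim_lo) / (clim_hi - clim_lo)
            img, a = _render_image(spec.image_size, a_requested, g, spec.n_discs, rng)
            # the trait law uses the area fraction actually rendered, so the
            # image/trait coupling survives occasional placement failures
            trait = (
                spec.trait_base
                + spec.c_area * a
                + spec.c_green * g
                + spec.c_climate * clim
                + rng.normal(0.0, spec.sigma_noise)
            )
            if trait <= 0:
                raise ValueError("generated a non-positive trait value; adjust the spec")
            images[rid] = img
            Image.fromarray((img * 255).round().astype(np.uint8)).save(image_dir / f"{rid}.png")
            unc = float(rng.uniform(0.0, 20.0)) if rng.random() > 0.1 else np.nan
            rows_occ.append((rid, species, f"images/{rid}.png", lat, lon, unc))
            rows_gt.append((rid, species, a, a_requested, g, clim, trait, lat, lon))
            latents.append(trait)
        mu = float(np.mean(latents))
        if spec.trait_records_per_species <= 1 or spec.sd_frac == 0:
            rows_trait.append((species, spec.trait_id, mu))
        else:
            draws = rng.normal(mu, spec.sd_frac * mu, size=spec.trait_records_per_species)
            draws = np.clip(draws, mu * 0.2, None)  # keep values positive
            for v in draws:
                rows_trait.append((species, spec.trait_id, float(v)))

    gt = pd.DataFrame(
        rows_gt,
        columns=["record_id", "species", "area_frac", "area_frac_requested",
                 "greenness", "clim_norm", "trait", "lat", "lon"],
    )
    trait_csv = out_dir / "traits.csv"
    occ_csv = out_dir / "occurrences.csv"
    pd.DataFrame(rows_trait, columns=["species", "trait_id", "value"]).to_csv(trait_csv, index=False)
    pd.DataFrame(
        rows_occ,
        columns=["record_id", "species", "image_ref", "lat", "lon", "coord_uncertainty_km"],
    ).to_csv(occ_csv, index=False)
    gt.to_csv(out_dir / "ground_truth.csv", index=False)
    logger.info("generated synthetic corpus: %d species, %d images", spec.n_species, rec)
    return SyntheticCorpus(
        out_dir=out_dir,
        trait_csv=trait_csv,
        occurrence_csv=occ_csv,
        image_dir=image_dir,
        climate_dir=climate_dir,
        ground_truth=gt,
        images=images,
    )
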