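"""Ingestion of geolocated photograph occurrence records.

Occurrence exports (GBIF/iNaturalist style) carry a species name, an image
reference and a WGS84 geolocation with an optional coordinate-uncertainty
radius. Records are screened for geospatial quality and then annotated with
six bioclimatic predictors sampled from climate rasters at the photo
location: BIO1 (annual mean temperature), BIO4 (temperature seasonality),
BIO7 (temperature annual range), BIO12 (annual precipitation), BIO15
(precipitation seasonality) and the derived precipitation annual range
BIO13 − BIO14.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .rasters import Raster, read_raster

__all__ = [
    "BIOCLIM_LAYERS",
    "BIOCLIM_VARS",
    "PhotoRecord",
    "BioclimVector",
    "filter_occurrences",
    "extract_bioclim",
    "read_occurrence_csv",
    "load_bioclim_rasters",
    "bioclim_to_frame",
]

logger = logging.getLogger(__name__)

#: raster layers required on disk
BIOCLIM_LAYERS = ("bio1", "bio4", "bio7", "bio12", "bio13", "bio14", "bio15")
#: predictor columns fed to the models (bio13_14 = bio13 − bio14)
BIOCLIM_VARS = ("bio1", "bio4", "bio7", "bio12", "bio15", "bio13_14")


@dataclass(frozen=True)
class PhotoRecord:
    """One photograph occurrence: identifier, taxon, image and geolocation."""

    record_id: str
    species: str
    image_ref: str
    lat: float | None
    lon: float | None
    coord_uncertainty_km: float | None = None


@dataclass(frozen=True)
class BioclimVector:
    """The six bioclimatic predictors at one location."""

    bio1: float
    bio4: float
    bio7: float
    bio12: float
    bio15: float
    bio13_14: float

    def as_array(self) -> np.ndarray:
        return np.array([self.bio1, self.bio4, self.bio7, self.bio12, self.bio15, self.bio13_14])


def _valid_coords(rec: PhotoRecord) -> bool:
    if rec.lat is None or rec.lon is None:
        return False
    if not (math.isfinite(rec.lat) and math.isfinite(rec.lon)):
        return False
    return -90.0 <= rec.lat <= 90.0 and -180.0 <= rec.lon <= 180.0


def filter_occurrences(
    records: Sequence[PhotoRecord],
    max_uncertainty_km: float = 100.0,
    species_allowlist: Iterable[str] | None = None,
) -> list[PhotoRecord]:
    """Drop records with missing/out-of-bounds coordinates or excessive uncertainty.

    The uncertainty rule is "more than ``max_uncertainty_km``", so a record at
    exactly the threshold survives, as does one with unknown uncertainty.
    ``species_allowlist`` optionally restricts to trusted names (screening of
    presumed misidentifications is delegated to the caller). Idempotent;
    order preserved; per-reason drop counts are logged.
    """
    if max_uncertainty_km <= 0:
        raise ValueError("max_uncertainty_km must be positive")
    allow = None
    if species_allowlist is not None:
        from .traits import normalize_species_name

        allow = {normalize_species_name(s) for s in species_allowlist}
    kept: list[PhotoRecord] = []
    drops = {"coords": 0, "uncertainty": 0, "species": 0}
    for rec in records:
        if not _valid_coords(rec):
            drops["coords"] += 1
            continue
        unc = rec.coord_uncertainty_km
        if unc is not None and math.isfinite(unc) and unc > max_uncertainty_km:
            drops["uncertainty"] += 1
            continue
        if allow is not None:
            from .traits import normalize_species_name

            if normalize_species_name(rec.species) not in allow:
                drops["species"] += 1
                continue
        kept.append(rec)
    if any(drops.values()):
        logger.info(
            "occurrence filter dropped %d (coords), %d (uncertainty > %g km), %d (species)",
            drops["coords"], drops["uncertainty"], max_uncertainty_km, drops["species"],
        )
    return kept


def extract_bioclim(
    records: Sequence[PhotoRecord], rasters: Mapping[str, Raster]
) -> list[tuple[str, BioclimVector]]:
    """Sample the seven climate layers at each record's location.

    Values come from the raster cell containing the point (no
    interpolation). Records falling on a no-data cell in any layer — e.g.
    geolocations off the land surface — are excluded from the output.
    """
    missing = [name for name in BIOCLIM_LAYERS if name not in rasters]
    if missing:
        raise ValueError(f"missing bioclim raster layer(s): {missing}")
    out: list[tuple[str, BioclimVector]] = []
    n_nodata = 0
    for rec in records:
        vals = {}
        ok = True
        for name in BIOCLIM_LAYERS:
            v = float(rasters[name].sample(rec.lat, rec.lon)[0])
            if not math.isfinite(v):
                ok = False
                break
            vals[name] = v
        if not ok:
            n_nodata += 1
            continue
        out.append(
            (
                rec.record_id,
                BioclimVector(
                    bio1=vals["bio1"],
                    bio4=vals["bio4"],
                    bio7=vals["bio7"],
                    bio12=vals["bio12"],
                    bio15=vals["bio15"],
                    bio13_14=vals["bio13"] - vals["bio14"],
                ),
            )
        )
    if n_nodata:
        logger.info("dropped %d record(s) on no-data climate cells", n_nodata)
    return out


def read_occurrence_csv(path: str | Path) -> list[PhotoRecord]:
    """Read occurrences with columns record_id,species,image_ref,lat,lon,coord_uncertainty_km."""
    df = pd.read_csv(path)
    required = {"record_id", "species", "image_ref", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV {path} lacks columns: {sorted(missing)}")
    if "coord_uncertainty_km" not in df.columns:
        df["coord_uncertainty_km"] = np.nan

    def opt(x) -> float | None:
        x = float(x) if x is not None and str(x) != "" else float("nan")
        return None if math.isnan(x) else x

    ids = df["record_id"].astype(str)
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].head(3).tolist()
        raise ValueError(f"duplicate record_id values in {path}: {dupes} ...")
    return [
        PhotoRecord(
            record_id=str(r.record_id),
            species=str(r.species),
            image_ref=str(r.image_ref),
            lat=opt(r.lat),
            lon=opt(r.lon),
            coord_uncertainty_km=opt(r.coord_uncertainty_km),
        )
        for r in df.itertuples(index=False)
    ]


def load_bioclim_rasters(clim_dir: str | Path, suffix: str = ".asc") -> dict[str, Raster]:
    """Load bio1..bio15 layers named ``bio<k>.asc`` (or ``.tif``) from a directory."""
    clim_dir = Path(clim_dir)
    rasters = {}
    for name in BIOCLIM_LAYERS:
        path = clim_dir / f"{name}{suffix}"
        if not path.exists():
            alt = clim_dir / f"{name}.tif"
            path = alt if alt.exists() else path
        if not path.exists():
            raise ValueError(f"missing bioclim raster layer: {name} (looked for {path})")
        rasters[name] = read_raster(path)
    return rasters


def bioclim_to_frame(pairs: Iterable[tuple[str, BioclimVector]]) -> pd.DataFrame:
    rows = [(rid, *v.as_array()) for rid, v in pairs]
    return pd.DataFrame(rows, columns=["record_id", *BIOCLIM_VARS])
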