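"""Ingestion of species-level trait tables.

Trait databases such as TRY distribute one row per measurement, already
converted to a standard unit per trait. This module filters gross outliers
with a pooled z-score rule and reduces the table to per-species summary
statistics (mean, standard deviation, observation count), which are the
weak labels the image models train on.

Supported traits: leaf area (LA), growth height (GH), specific leaf area
(SLA), leaf nitrogen concentration (LNC), seed mass (SM) and stem specific
density (SSD).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRAIT_IDS",
    "TraitRecord",
    "SpeciesTraitStats",
    "remove_trait_outliers",
    "compute_species_stats",
    "read_trait_csv",
    "stats_to_frame",
    "write_stats_csv",
    "read_stats_csv",
    "normalize_species_name",
]

logger = logging.getLogger(__name__)

TRAIT_IDS = ("LA", "GH", "SLA", "LNC", "SM", "SSD")


def normalize_species_name(name: str) -> str:
    """Canonical species key: trimmed, internal whitespace collapsed, case-folded.

    Matching between trait tables and occurrence records is exact on this
    key; no taxonomic synonym resolution is attempted.
    """
    return " ".join(str(name).split()).casefold()


@dataclass(frozen=True)
class TraitRecord:
    """One trait measurement in the trait's standardized unit."""

    species: str
    trait_id: str
    value: float

    def __post_init__(self) -> None:
        if not str(self.species).strip():
            raise ValueError("species name must be non-empty")
        if self.trait_id not in TRAIT_IDS:
            raise ValueError(f"unknown trait_id {self.trait_id!r}; expected one of {TRAIT_IDS}")
        if not (self.value > 0):
            raise ValueError(f"trait value must be > 0, got {self.value!r} for {self.species!r}")


@dataclass(frozen=True)
class SpeciesTraitStats:
    """Per-species trait mean and standard deviation in original units."""

    species: str
    trait_id: str
    mean: float
    sd: float
    n_obs: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")
        if self.n_obs == 1 and self.sd != 0:
            raise ValueError("a single observation has sd == 0 by definition")


def remove_trait_outliers(records: Sequence[TraitRecord], z_max: float = 4.0) -> list[TraitRecord]:
    """Drop records deviating from the pooled mean by more than ``z_max`` pooled SDs.

    The pooled mean and (sample) standard deviation are computed over the
    current set of records of the one trait present, and the filter is
    repeated until no record exceeds the threshold, so the returned set is
    a fixed point (re-applying the filter changes nothing). A degenerate
    pool (SD == 0) retains everything. Order is preserved.
    """
    if z_max <= 0:
        raise ValueError("z_max must be positive")
    kept = list(records)
    if not kept:
        return []
    trait_ids = {r.trait_id for r in kept}
    if len(trait_ids) > 1:
        raise ValueError(f"records mix trait_ids {sorted(trait_ids)}; filter one trait at a time")
    n_input = len(kept)
    while True:
        values = np.array([r.value for r in kept], dtype=float)
        sd = values.std(ddof=1) if len(values) > 1 else 0.0
        if sd == 0:
            break
        z = np.abs(values - values.mean()) / sd
        if np.all(z <= z_max):
            break
        kept = [r for r, zi in zip(kept, z) if zi <= z_max]
    n_removed = n_input - len(kept)
    if n_removed:
        logger.info("removed %d/%d outlier records (|z| > %g)", n_removed, n_input, z_max)
    return kept


def compute_species_stats(records: Iterable[TraitRecord]) -> list[SpeciesTraitStats]:
    """Aggregate records to one (species, trait) row of mean, sample SD and count.

    SD uses the n−1 denominator; a species with one observation gets sd 0.
    Output is sorted by (trait_id, species key) for reproducibility.
    """
    groups: dict[tuple[str, str], list[float]] = {}
    names: dict[tuple[str, str], str] = {}
    for r in records:
        key = (r.trait_id, normalize_species_name(r.species))
        groups.setdefault(key, []).append(r.value)
        names.setdefault(key, " ".join(str(r.species).split()))
    out = []
    for key in sorted(groups):
        vals = np.asarray(groups[key], dtype=float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out.append(
            SpeciesTraitStats(
                species=names[key],
                trait_id=key[0],
                mean=float(vals.mean()),
                sd=sd,
                n_obs=len(vals),
            )
        )
    return out


def read_trait_csv(path: str | Path) -> list[TraitRecord]:
    """Read a long-format trait table with columns species, trait_id, value.

    A TRY-style export with one column per trait can be melted to this shape
    with :func:`pandas.melt`; see the README for a recipe.
    """
    df = pd.read_csv(path)
    missing = {"species", "trait_id", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"trait CSV {path} lacks columns: {sorted(missing)}")
    return [
        TraitRecord(str(row.species), str(row.trait_id), float(row.value))
        for row in df.itertuples(index=False)
        if math.isfinite(float(row.value))
    ]


def stats_to_frame(stats: Iterable[SpeciesTraitStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.species, s.trait_id, s.mean, s.sd, s.n_obs) for s in stats],
        columns=["species", "trait_id", "mean", "sd", "n_obs"],
    )


def write_stats_csv(stats: Iterable[SpeciesTraitStats], path: str | Path) -> None:
    stats_to_frame(stats).to_csv(path, index=False)


def read_stats_csv(path: str | Path) -> list[SpeciesTraitStats]:
    df = pd.read_csv(path)
    return [
        SpeciesTraitStats(str(r.species), str(r.trait_id), float(r.mean), float(r.sd), int(r.n_obs))
        for r in df.itertuples(index=False)
    ]
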