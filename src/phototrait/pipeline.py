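"""End-to-end dataset assembly from raw input files.

Chains the ingestion modules: trait table → outlier filter → species
stats; occurrence table → geospatial filter → bioclim extraction; then
linkage, per-species sampling, log-target trimming, splitting and
normalizer fitting. This is the programmatic counterpart of running the
``ingest-traits``, ``ingest-occurrences`` and ``build-dataset`` CLI steps.
"""

from __future__ import annotations

from pathlib import Path

from .datasets import (
    DatasetSplit,
    NormalizationParams,
    fit_split_normalizers,
    link_and_sample,
    log_transform_and_trim,
    make_split,
)
from .occurrences import extract_bioclim, filter_occurrences, load_bioclim_rasters, read_occurrence_csv
from .traits import compute_species_stats, read_trait_csv, remove_trait_outliers

__all__ = ["build_trait_dataset"]


def build_trait_dataset(
    trait_csv: str | Path,
    occurrence_csv: str | Path,
    clim_dir: str | Path | None = None,
    trait_id: str = "LA",
    max_per_species: int = 8,
    test_frac: float = 0.1,
    seed: int = 0,
    z_max: float = 4.0,
    k_sd: float = 3.0,
    max_uncertainty_km: float = 100.0,
) -> tuple[DatasetSplit, NormalizationParams, dict[str, NormalizationParams] | None]:
    """Build a ready-to-train split from raw CSVs (and optional climate rasters).

    Returns the split plus the train-only target and bioclim normalization
    parameters (the latter ``None`` when ``clim_dir`` is not given).
    """
    records = [r for r in read_trait_csv(trait_csv) if r.trait_id == trait_id]
    if not records:
        raise ValueError(f"no records for trait {trait_id!r} in {trait_csv}")
    stats = compute_species_stats(remove_trait_outliers(records, z_max))
    photos = filter_occurrences(read_occurrence_csv(occurrence_csv), max_uncertainty_km)
    bioclim = None
    if clim_dir is not None:
        rasters = load_bioclim_rasters(clim_dir)
        bioclim = dict(extract_bioclim(photos, rasters))
    obs = link_and_sample(stats, photos, max_per_species, seed, bioclim=bioclim)
    obs = log_transform_and_trim(obs, k_sd)
    split = make_split(obs, test_frac=test_frac, seed=seed)
    target_params, bioclim_params = fit_split_normalizers(split)
    return split, target_params, bioclim_params
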