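"""Dataset assembly: trait–photo linkage, sampling, splits and target scaling.

Species-level trait statistics are joined to photograph records by species
name, with a per-species cap on the number of images so that the model sees
many species rather than many photos of a few. Targets are the species
trait means, log10-transformed (trait distributions are strongly
right-skewed) and min–max normalized with statistics from the training
split only, which keeps validation and test information out of the scaling.

The "plasticity" target augmentation replaces the fixed species mean by a
fresh draw from a Gaussian centred on the species mean and truncated at one
standard deviation, every time an observation is presented during training.
This tells the network that a species realises a range of trait values, not
a point.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .occurrences import BIOCLIM_VARS, BioclimVector, PhotoRecord
from .traits import SpeciesTraitStats, normalize_species_name

__all__ = [
    "LinkedObservation",
    "DatasetSplit",
    "NormalizationParams",
    "link_and_sample",
    "log_transform_and_trim",
    "make_split",
    "fit_normalizer",
    "normalize",
    "denormalize",
    "plasticity_augment",
    "plasticity_targets",
    "truncated_species_draws",
    "normalized_targets",
    "fit_split_normalizers",
    "split_to_frames",
    "save_split",
    "load_split",
]

logger = logging.getLogger(__name__)


@dataclass
class LinkedObservation:
    """One photograph linked to its species trait statistics and climate."""

    record_id: str
    species: str
    image_ref: str
    trait_mean: float
    trait_sd: float
    bioclim: BioclimVector | None = None
    lat: float | None = None
    lon: float | None = None
    target_norm: float | None = None

    @property
    def log_target(self) -> float:
        return float(np.log10(self.trait_mean))


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partitions plus the seed that made them."""

    train: list[LinkedObservation]
    validation: list[LinkedObservation]
    test: list[LinkedObservation]
    seed: int

    def __post_init__(self) -> None:
        ids = [o.record_id for part in (self.train, self.validation, self.test) for o in part]
        if len(ids) != len(set(ids)):
            raise ValueError("split partitions are not disjoint by record_id")

    @property
    def n_total(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


@dataclass
class NormalizationParams:
    """Train-only extrema of a (log-transformed) quantity for min–max scaling.

    ``target_norm = (target − min_train) / (max_train − min_train)``; training
    values land exactly in [0, 1], validation/test values approximately so
    and are not clipped at normalization time.
    """

    min_train: float
    max_train: float

    def __post_init__(self) -> None:
        if not self.max_train > self.min_train:
            raise ValueError("max_train must exceed min_train (zero target range)")

    @property
    def range(self) -> float:
        return self.max_train - self.min_train


def link_and_sample(
    stats: Sequence[SpeciesTraitStats],
    photos: Sequence[PhotoRecord],
    max_per_species: int,
    seed: int,
    bioclim: dict[str, BioclimVector] | None = None,
) -> list[LinkedObservation]:
    """Join photos to species trait stats, keeping ≤ ``max_per_species`` photos each.

    For every species present in both tables, min(count, max_per_species)
    photos are drawn uniformly without replacement with the given seed.
    When a ``bioclim`` mapping (record_id → vector) is given, photos without
    an entry are skipped (they could not be linked to climate data).
    """
    if max_per_species < 1:
        raise ValueError("max_per_species must be >= 1")
    rng = np.random.default_rng(seed)
    stats_by_species = {normalize_species_name(s.species): s for s in stats}
    photos_by_species: dict[str, list[PhotoRecord]] = {}
    for p in photos:
        if bioclim is not None and p.record_id not in bioclim:
            continue
        photos_by_species.setdefault(normalize_species_name(p.species), []).append(p)
    out: list[LinkedObservation] = []
    for key in sorted(set(stats_by_species) & set(photos_by_species)):
        st = stats_by_species[key]
        cand = photos_by_species[key]
        k = min(len(cand), max_per_species)
        idx = rng.choice(len(cand), size=k, replace=False) if len(cand) > k else np.arange(len(cand))
        for i in sorted(int(j) for j in idx):
            p = cand[i]
            out.append(
                LinkedObservation(
                    record_id=p.record_id,
                    species=st.species,
                    image_ref=p.image_ref,
                    trait_mean=st.mean,
                    trait_sd=st.sd,
                    bioclim=None if bioclim is None else bioclim[p.record_id],
                    lat=p.lat,
                    lon=p.lon,
                )
            )
    return out


def log_transform_and_trim(obs: Sequence[LinkedObservation], k_sd: float = 3.0) -> list[LinkedObservation]:
    """Drop observations whose log10 target lies > ``k_sd`` SDs from the mean.

    The mean/SD are of the log10-transformed targets of the input set; a
    degenerate SD of zero retains everything. Runs once per trait dataset,
    before splitting, so the trim cannot depend on the split.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    obs = list(obs)
    if not obs:
        return []
    for o in obs:
        if not o.trait_mean > 0:
            raise ValueError(f"non-positive trait value for record {o.record_id!r}")
    logs = np.array([o.log_target for o in obs])
    sd = logs.std(ddof=1) if len(logs) > 1 else 0.0
    if sd == 0:
        return obs
    keep = np.abs(logs - logs.mean()) <= k_sd * sd
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("log-target trim removed %d/%d observations (> %g SD)", n_removed, len(obs), k_sd)
    return [o for o, k in zip(obs, keep) if k]


def make_split(
    obs: Sequence[LinkedObservation],
    test_frac: float = 0.1,
    seed: int = 0,
    n_test: int | None = None,
) -> DatasetSplit:
    """Random test split plus a 4:1 train/validation split of the remainder.

    The test set receives round(test_frac·N) records (or exactly ``n_test``
    when given, to reproduce a published split); of the remaining R records
    the validation set receives floor(R/5) and training the rest.
    """
    obs = list(obs)
    n = len(obs)
    if n < 10:
        raise ValueError("need at least 10 observations to split")
    if n_test is None:
        if not 0 < test_frac < 1:
            raise ValueError("test_frac must be in (0, 1)")
        n_test = int(round(test_frac * n))
    if not 0 < n_test < n:
        raise ValueError(f"test size {n_test} leaves an empty partition (N={n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test_idx = set(order[:n_test].tolist())
    remainder = [obs[i] for i in order[n_test:]]
    n_val = len(remainder) // 5
    if n_val == 0 or len(remainder) - n_val == 0:
        raise ValueError("split leaves an empty train or validation partition")
    split = DatasetSplit(
        train=remainder[n_val:],
        validation=remainder[:n_val],
        test=[obs[i] for i in sorted(test_idx)],
        seed=seed,
    )
    logger.info(
        "split N=%d into train=%d validation=%d test=%d",
        n, len(split.train), len(split.validation), len(split.test),
    )
    return split


def fit_normalizer(train_targets: Sequence[float]) -> NormalizationParams:
    """Min–max parameters from the *training* targets only (no leakage)."""
    arr = np.asarray(train_targets, dtype=float)
    if arr.size < 2 or np.unique(arr).size < 2:
        raise ValueError("need at least two distinct training targets to normalize")
    return NormalizationParams(min_train=float(arr.min()), max_train=float(arr.max()))


def normalize(x, p: NormalizationParams):
    """Min–max scale; training values map into [0, 1], others may exceed it."""
    return (np.asarray(x, dtype=float) - p.min_train) / p.range


def denormalize(y, p: NormalizationParams):
    return np.asarray(y, dtype=float) * p.range + p.min_train


def plasticity_augment(
    obs: LinkedObservation, p: NormalizationParams, rng: np.random.Generator
) -> float:
    """One augmented normalized target drawn from the species trait distribution.

    Draws v ~ Normal(μ, σ) truncated to [μ−σ, μ+σ] in original trait units,
    then returns clip(normalize(log10 v), 0, 1). σ == 0 returns the plain
    normalized target. A fresh draw is made at every presentation.
    """
    return float(plasticity_targets([obs], p, rng)[0])


def plasticity_targets(
    obs: Sequence[LinkedObservation], p: NormalizationParams, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized :func:`plasticity_augment` for a batch of observations."""
    mu = np.array([o.trait_mean for o in obs], dtype=float)
    sd = np.array([o.trait_sd for o in obs], dtype=float)
    out = np.empty(len(obs), dtype=float)
    fixed = sd == 0
    out[fixed] = np.clip(normalize(np.log10(mu[fixed]), p), 0.0, 1.0)
    if (~fixed).any():
        draws = truncated_species_draws(mu[~fixed], sd[~fixed], rng)
        out[~fixed] = np.clip(normalize(np.log10(draws), p), 0.0, 1.0)
    return out


def truncated_species_draws(
    mu, sd, rng: np.random.Generator, size: int | tuple | None = None
) -> np.ndarray:
    """Original-unit draws from Normal(μ, σ) truncated to [μ−σ, μ+σ].

    Species whose interval would cross zero get the lower bound floored at
    the smallest positive float (with a warning) so log10 stays defined.
    """
    mu = np.asarray(mu, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("truncated draws require sd > 0 (sd == 0 targets are deterministic)")
    lo = mu - sd
    bad = lo <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(np.sum(bad))} species have mean - sd <= 0; flooring the truncation "
            "interval at the smallest positive value to keep log10 defined",
            RuntimeWarning,
            stacklevel=2,
        )
        lo = np.where(bad, np.finfo(float).tiny, lo)
    a = (lo - mu) / sd
    b = np.ones_like(a)  # upper bound μ+σ is one SD above the mean
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def normalized_targets(obs: Sequence[LinkedObservation], p: NormalizationParams) -> np.ndarray:
    """Deterministic normalized log10 species-mean targets (no augmentation)."""
    return normalize(np.log10([o.trait_mean for o in obs]), p)


def fit_split_normalizers(
    split: DatasetSplit,
) -> tuple[NormalizationParams, dict[str, NormalizationParams] | None]:
    """Target and per-bioclim-variable min–max params from the training split only."""
    target_params = fit_normalizer([o.log_target for o in split.train])
    bioclim_params = None
    if split.train and split.train[0].bioclim is not None:
        mat = np.array([o.bioclim.as_array() for o in split.train])
        bioclim_params = {
            name: fit_normalizer(mat[:, j]) for j, name in enumerate(BIOCLIM_VARS)
        }
    # annotate normalized targets on every observation (train lands in [0,1])
    for part in (split.train, split.validation, split.test):
        for o in part:
            o.target_norm = float(normalize(o.log_target, target_params))
    return target_params, bioclim_params


# ---------------------------------------------------------------------------
# manifests


def _obs_row(o: LinkedObservation) -> dict:
    row = {
        "record_id": o.record_id,
        "species": o.species,
        "image_ref": o.image_ref,
        "trait_mean": o.trait_mean,
        "trait_sd": o.trait_sd,
        "lat": o.lat,
        "lon": o.lon,
        "target_norm": o.target_norm,
    }
    if o.bioclim is not None:
        row.update(dict(zip(BIOCLIM_VARS, o.bioclim.as_array())))
    return row


def split_to_frames(split: DatasetSplit) -> dict[str, pd.DataFrame]:
    return {
        part: pd.DataFrame([_obs_row(o) for o in getattr(split, part)])
        for part in ("train", "validation", "test")
    }


def save_split(
    split: DatasetSplit,
    out_dir: str | Path,
    target_params: NormalizationParams | None = None,
    bioclim_params: dict[str, NormalizationParams] | None = None,
) -> None:
    """Write per-partition manifest CSVs and a JSON sidecar with scaling params."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for part, df in split_to_frames(split).items():
        df.to_csv(out_dir / f"{part}.csv", index=False)
    sidecar = {
        "seed": split.seed,
        "n": {p: len(getattr(split, p)) for p in ("train", "validation", "test")},
        "target_params": None
        if target_params is None
        else {"min_train": target_params.min_train, "max_train": target_params.max_train},
        "bioclim_params": None
        if bioclim_params is None
        else {k: {"min_train": v.min_train, "max_train": v.max_train} for k, v in bioclim_params.items()},
    }
    (out_dir / "normalization.json").write_text(json.dumps(sidecar, indent=2))


def load_split(out_dir: str | Path) -> tuple[DatasetSplit, NormalizationParams | None, dict | None]:
    out_dir = Path(out_dir)
    parts = {}
    for part in ("train", "validation", "test"):
        df = pd.read_csv(out_dir / f"{part}.csv")
        obs = []
        for r in df.itertuples(index=False):
            bio = None
            if all(v in df.columns for v in BIOCLIM_VARS):
                vals = [getattr(r, v) for v in BIOCLIM_VARS]
                bio = BioclimVector(*vals)
            obs.append(
                LinkedObservation(
                    record_id=str(r.record_id),
                    species=str(r.species),
                    image_ref=str(r.image_ref),
                    trait_mean=float(r.trait_mean),
                    trait_sd=float(r.trait_sd),
                    bioclim=bio,
                    lat=None if pd.isna(r.lat) else float(r.lat),
                    lon=None if pd.isna(r.lon) else float(r.lon),
                )
            )
        parts[part] = obs
    meta = json.loads((out_dir / "normalization.json").read_text())
    split = DatasetSplit(parts["train"], parts["validation"], parts["test"], seed=meta["seed"])
    tp = meta.get("target_params")
    target_params = None if tp is None else NormalizationParams(**tp)
    bp = meta.get("bioclim_params")
    bioclim_params = None if bp is None else {k: NormalizationParams(**v) for k, v in bp.items()}
    return split, target_params, bioclim_params
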