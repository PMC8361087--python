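"""Model evaluation: MAE/NMAE/R², ensembles, cross-validation, robustness.

The headline statistic is the normalised mean absolute error,
``NMAE = 100 · MAE / (max(target) − min(target))`` on the test set, which
makes errors comparable across traits with different units and ranges. R²
is the explained variance of the linear fit of predictions versus targets,
i.e. the squared Pearson correlation. Ensembles average member predictions
element-wise. The robustness analysis compares MAEs across annotation
categories (growth form, image quality, image-target distance) with a
nonparametric k-sample rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import DatasetSplit, LinkedObservation, make_split

__all__ = [
    "EvalMetrics",
    "AnnotatedPrediction",
    "GROWTH_FORMS",
    "IMAGE_QUALITIES",
    "TARGET_DISTANCES",
    "compute_metrics",
    "ensemble_predict",
    "cross_validate",
    "grouped_mae",
]

GROWTH_FORMS = ("woody", "non_woody")
IMAGE_QUALITIES = ("low", "medium", "high")
TARGET_DISTANCES = ("lt_1m", "m1_5", "gt_5m")


@dataclass(frozen=True)
class EvalMetrics:
    """MAE, range-normalised MAE (percent) and R² over n prediction pairs."""

    mae: float
    nmae: float
    r2: float
    n: int

    def __str__(self) -> str:
        return f"MAE {self.mae:.4f}  NMAE {self.nmae:.2f}%  R2 {self.r2:.3f}  (n={self.n})"


@dataclass(frozen=True)
class AnnotatedPrediction:
    """A prediction/target pair with the manual robustness annotations."""

    record_id: str
    prediction: float
    target: float
    growth_form: str | None = None
    image_quality: str | None = None
    target_distance: str | None = None

    def __post_init__(self) -> None:
        for value, valid in (
            (self.growth_form, GROWTH_FORMS),
            (self.image_quality, IMAGE_QUALITIES),
            (self.target_distance, TARGET_DISTANCES),
        ):
            if value is not None and value not in valid:
                raise ValueError(f"invalid category {value!r}; expected one of {valid}")
        if not (np.isfinite(self.prediction) and np.isfinite(self.target)):
            raise ValueError("prediction and target must be finite")


def compute_metrics(pred, target) -> EvalMetrics:
    """MAE, NMAE (% of target range) and squared Pearson correlation.

    Constant targets have no range, so NMAE is undefined and rejected;
    constant predictions have no correlation and report r2 = 0.
    """
    pred = np.asarray(pred, dtype=float).reshape(-1)
    target = np.asarray(target, dtype=float).reshape(-1)
    if pred.shape != target.shape or pred.size == 0:
        raise ValueError("predictions and targets must be equal-length, non-empty vectors")
    mae = float(np.mean(np.abs(pred - target)))
    target_range = float(target.max() - target.min())
    if target_range == 0:
        raise ValueError("target range is zero; NMAE is undefined")
    nmae = 100.0 * mae / target_range
    if pred.size < 2 or np.all(pred == pred[0]):
        r2 = 0.0
    else:
        r = np.corrcoef(pred, target)[0, 1]
        r2 = float(r * r) if np.isfinite(r) else 0.0
    return EvalMetrics(mae=mae, nmae=nmae, r2=r2, n=pred.size)


def ensemble_predict(member_predictions: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean of aligned member prediction vectors."""
    if len(member_predictions) == 0:
        raise ValueError("need at least one ensemble member")
    arrays = [np.asarray(m, dtype=float).reshape(-1) for m in member_predictions]
    lengths = {a.shape[0] for a in arrays}
    if len(lengths) > 1:
        raise ValueError(f"member prediction lengths differ: {sorted(lengths)}")
    return np.mean(arrays, axis=0)


def cross_validate(
    obs: Sequence[LinkedObservation],
    fit_predict: Callable[[DatasetSplit, int], np.ndarray],
    k: int = 3,
    test_frac: float = 0.1,
    seed: int = 0,
) -> tuple[list[EvalMetrics], pd.DataFrame]:
    """k-fold evaluation with disjoint test folds and re-randomized splits.

    The shuffled observations are partitioned into ``k`` disjoint test
    folds of round(test_frac·N) records each; per fold the remaining data
    is split 4:1 into train/validation with a fold-specific seed and
    ``fit_predict(split, fold_seed)`` must return test-set predictions on
    the target scale. Returns per-fold metrics plus the pooled
    (record_id, target, prediction, fold) pairs (N = k × N_test).
    """
    obs = list(obs)
    if k < 2:
        raise ValueError("k must be >= 2")
    n_test = int(round(test_frac * len(obs)))
    if k * n_test > len(obs) or n_test == 0:
        raise ValueError(f"insufficient data for {k} disjoint test folds of {n_test}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(obs))
    metrics: list[EvalMetrics] = []
    rows = []
    from .datasets import normalized_targets  # local import to avoid cycle at module load

    for fold in range(k):
        test_idx = order[fold * n_test : (fold + 1) * n_test]
        rest_idx = np.concatenate([order[: fold * n_test], order[(fold + 1) * n_test :]])
        fold_seed = seed + 1000 * (fold + 1)
        fold_rng = np.random.default_rng(fold_seed)
        rest = [obs[i] for i in fold_rng.permutation(rest_idx)]
        n_val = len(rest) // 5
        split = DatasetSplit(
            train=rest[n_val:],
            validation=rest[:n_val],
            test=[obs[i] for i in test_idx],
            seed=fold_seed,
        )
        pred = np.asarray(fit_predict(split, fold_seed), dtype=float).reshape(-1)
        target = np.array([np.log10(o.trait_mean) for o in split.test])
        if pred.shape != target.shape:
            raise ValueError("fit_predict returned a vector of the wrong length")
        metrics.append(compute_metrics(pred, target))
        rows.extend(
            (o.record_id, t, p, fold)
            for o, t, p in zip(split.test, target, pred)
        )
    pooled = pd.DataFrame(rows, columns=["record_id", "target", "prediction", "fold"])
    return metrics, pooled


def grouped_mae(
    preds: Sequence[AnnotatedPrediction], by: str
) -> tuple[pd.DataFrame, float]:
    """Per-category MAE and share, plus a Kruskal–Wallis p-value on |errors|.

    ``by`` is one of ``growth_form``, ``image_quality``, ``target_distance``.
    Categories with no members are reported with share 0% and no MAE; the
    rank test runs over the non-empty categories and needs at least two.
    """
    valid_fields = {
        "growth_form": GROWTH_FORMS,
        "image_quality": IMAGE_QUALITIES,
        "target_distance": TARGET_DISTANCES,
    }
    if by not in valid_fields:
        raise ValueError(f"unknown grouping field {by!r}; expected one of {sorted(valid_fields)}")
    errors: dict[str, list[float]] = {c: [] for c in valid_fields[by]}
    for p in preds:
        cat = getattr(p, by)
        if cat is not None:
            errors[cat].append(abs(p.prediction - p.target))
    total = sum(len(v) for v in errors.values())
    if total == 0:
        raise ValueError(f"no annotations present for field {by!r}")
    rows = [
        {
            "category": cat,
            "n": len(errs),
            "share_pct": 100.0 * len(errs) / total,
            "mae": float(np.mean(errs)) if errs else np.nan,
        }
        for cat, errs in errors.items()
    ]
    groups = [np.asarray(v) for v in errors.values() if len(v) > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty categories for the rank test")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # all errors tied: no evidence of any difference
        p_value = 1.0
    else:
        _, p_value = stats.kruskal(*groups)
    return pd.DataFrame(rows), float(p_value)
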