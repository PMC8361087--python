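"""High-level modelling interface: build, fit and inspect trait regressors.

:class:`PhotoTraitModel` bundles a dataset split, its train-only scaling
parameters and a training configuration for one of the setups

* ``baseline``   — image-only CNN on species-mean targets,
* ``plasticity`` — image-only CNN, targets re-drawn each epoch from the
  truncated species trait distribution,
* ``worldclim``  — mixed image+climate CNN with plasticity targets.

``fit()`` returns a :class:`PhotoTraitResults` carrying the trained
network, the epoch history and test-set metrics, with ``summary()``,
``predict()`` and plotting helpers, so a full experiment reads::

    model = PhotoTraitModel(split, tparams, bparams, setup="worldclim", images=imgs)
    res = model.fit(max_epochs=10, seed=1)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import cnn as _cnn
from .datasets import (
    DatasetSplit,
    LinkedObservation,
    NormalizationParams,
    normalized_targets,
)
from .evaluation import EvalMetrics, compute_metrics, ensemble_predict
from .mapping import invert_targets

__all__ = ["SETUPS", "PhotoTraitModel", "PhotoTraitResults"]

SETUPS = ("baseline", "plasticity", "worldclim")


class PhotoTraitModel:
    """A trait-regression experiment on one dataset split.

    Parameters
    ----------
    split : DatasetSplit
        Disjoint train/validation/test observations.
    target_params : NormalizationParams
        Train-only min–max scaling of the log10 targets.
    bioclim_params : dict, optional
        Per-variable scaling of the climate predictors (required for the
        worldclim setup).
    setup : str
        One of ``baseline``, ``plasticity``, ``worldclim``.
    images : dict, optional
        Preloaded record_id → HWC float arrays; otherwise images are read
        from ``base_dir`` / each observation's ``image_ref``.
    """

    def __init__(
        self,
        split: DatasetSplit,
        target_params: NormalizationParams,
        bioclim_params: dict[str, NormalizationParams] | None = None,
        setup: str = "baseline",
        config: _cnn.TraitModelConfig | None = None,
        base_dir: str | Path | None = None,
        images: dict[str, np.ndarray] | None = None,
    ):
        if setup not in SETUPS:
            raise ValueError(f"unknown setup {setup!r}; expected one of {SETUPS}")
        if setup == "worldclim" and bioclim_params is None:
            raise ValueError("worldclim setup requires bioclim_params")
        self.split = split
        self.target_params = target_params
        self.bioclim_params = bioclim_params
        self.setup = setup
        self.config = config or _cnn.TraitModelConfig(
            image_size=64, mixed_data=(setup == "worldclim")
        )
        if setup == "worldclim" and not self.config.mixed_data:
            self.config = replace(self.config, mixed_data=True)
        self.base_dir = base_dir
        self.images = images

    def fit(self, max_epochs: int | None = None, seed: int | None = None) -> "PhotoTraitResults":
        """Train the network with early stopping and return the results."""
        cfg = self.config
        if max_epochs is not None or seed is not None:
            cfg = replace(
                cfg,
                max_epochs=cfg.max_epochs if max_epochs is None else max_epochs,
                seed=cfg.seed if seed is None else seed,
            )
        net = _cnn.build_model(cfg)
        history = _cnn.train(
            net,
            self.split,
            cfg,
            self.target_params,
            plasticity=self.setup in ("plasticity", "worldclim"),
            bioclim_params=self.bioclim_params,
            base_dir=self.base_dir,
            images=self.images,
        )
        return PhotoTraitResults(model=self, network=net, history=history, config=cfg)

    def _arrays(self, obs: Sequence[LinkedObservation]) -> tuple[np.ndarray, np.ndarray | None]:
        if self.images is not None:
            imgs = np.stack([self.images[o.record_id] for o in obs])
        else:
            imgs = _cnn.load_images(obs, self.config.image_size, self.base_dir)
        clim = None
        if self.setup == "worldclim":
            clim = _cnn.climate_matrix(obs, self.bioclim_params)
        return imgs, clim


@dataclass
class PhotoTraitResults:
    """A fitted trait regressor: trained weights, history and diagnostics."""

    model: PhotoTraitModel
    network: object
    history: _cnn.TrainingHistory
    config: _cnn.TraitModelConfig

    def predict(self, obs: Sequence[LinkedObservation], original_units: bool = False) -> np.ndarray:
        """Predictions for observations, on the normalized (or original) scale."""
        imgs, clim = self.model._arrays(obs)
        pred = self.network.predict(imgs, clim)
        if original_units:
            return invert_targets(pred, self.model.target_params)
        return pred

    def test_metrics(self) -> EvalMetrics:
        """MAE/NMAE/R² of the fitted model on the held-out test split."""
        obs = self.model.split.test
        pred = self.predict(obs)
        target = normalized_targets(obs, self.model.target_params)
        return compute_metrics(pred, target)

    def summary(self) -> str:
        """A compact text report of the experiment."""
        m = self.test_metrics()
        s = self.model.split
        lines = [
            "Photograph trait regression results",
            "=" * 51,
            f"setup:            {self.model.setup}",
            f"backbone:         {self.config.backbone}",
            f"parameters:       {self.network.n_params()}",
            f"train/val/test:   {len(s.train)}/{len(s.validation)}/{len(s.test)}",
            f"epochs trained:   {self.history.n_epochs} (best: "
            f"{'-' if self.history.best_epoch is None else self.history.best_epoch + 1})",
            f"final train MAE:  {self.history.train_mae[-1]:.4f}" if self.history.train_mae else
            "final train MAE:  -",
            f"test MAE:         {m.mae:.4f}",
            f"test NMAE:        {m.nmae:.2f}%",
            f"test R2:          {m.r2:.3f}",
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Train/validation MAE learning curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(1, self.history.n_epochs + 1)
        ax.plot(epochs, self.history.train_mae, label="train MAE")
        ax.plot(epochs, self.history.val_mae, label="validation MAE")
        ax.set_xlabel("epoch")
        ax.set_ylabel("MAE (normalized scale)")
        ax.legend()
        return ax

    @staticmethod
    def ensemble(
        results: Sequence["PhotoTraitResults"], obs: Sequence[LinkedObservation]
    ) -> np.ndarray:
        """Average member predictions over aligned observations."""
        return ensemble_predict([r.predict(obs) for r in results])
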