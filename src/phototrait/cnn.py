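"""CNN trait regressors: architectures, image pipeline and training loop.

Three training setups are supported on top of one architecture family:

* **baseline** — images only, species-mean targets;
* **plasticity** — images only, targets re-drawn each presentation from a
  Gaussian truncated at one standard deviation around the species mean;
* **worldclim** — plasticity targets plus a parallel dense branch ingesting
  the six normalized bioclimatic predictors (mixed-data model).

The regressor head follows the published layout: a global-average-pooled
image feature vector into dense layers of 512 → 1 units (image-only) or
512 → 4 units feeding, together with a 64 → 32 → 4 climate branch, a fusion
stack of 8 → 8 → 4 → 1 units; branch-final and output layers are linear,
every other dense layer is ReLU. Training uses mean squared error with
RMSprop (batch 20, learning rate 0.001, inverse-time decay 0.0001) and
patience-based early stopping on the validation MAE with best-weight
restoration.

The fully functional backbone is ``tiny_test_cnn``, a small convolutional
stack sized for CPU experiments. The large published backbones
(Inception-ResNet-v2, Xception, half-width MobileNetV2) are recognised
configuration values but require a GPU deep-learning framework and
pretrained weights, neither of which this package ships; building them
raises :class:`BackboneUnavailableError`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from . import nn
from .datasets import (
    DatasetSplit,
    LinkedObservation,
    NormalizationParams,
    normalize,
    normalized_targets,
    plasticity_targets,
)
from .occurrences import BIOCLIM_VARS

__all__ = [
    "BACKBONES",
    "BackboneUnavailableError",
    "TraitModelConfig",
    "RegressorHeadSpec",
    "build_model",
    "augment_image",
    "preprocess_image",
    "load_images",
    "climate_matrix",
    "train",
    "TrainingHistory",
]

logger = logging.getLogger(__name__)

BACKBONES = ("inception_resnet_v2", "xception", "mobilenet_v2_half", "tiny_test_cnn")
_UNAVAILABLE_BACKBONES = ("inception_resnet_v2", "xception", "mobilenet_v2_half")


class BackboneUnavailableError(RuntimeError):
    """Raised for recognised backbones that need an external DL framework."""


@dataclass
class TraitModelConfig:
    """Architecture and training hyperparameters for one trait model."""

    backbone: str = "tiny_test_cnn"
    mixed_data: bool = False
    image_size: int = 512
    batch_size: int = 20
    lr: float = 0.001
    lr_decay: float = 0.0001
    loss: str = "mse"
    seed: int = 0
    max_epochs: int = 50
    patience: int = 5
    pretrained: bool = False
    augment: bool = True

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.loss != "mse":
            raise ValueError("only the 'mse' loss is supported")


@dataclass
class RegressorHeadSpec:
    """Layer widths of the regression head(s); defaults follow the published setup."""

    image_head_units: tuple[int, ...] = (512, 1)
    clim_branch_units: tuple[int, ...] = (64, 32, 4)
    fusion_units: tuple[int, ...] = (8, 8, 4, 1)

    def __post_init__(self) -> None:
        if self.image_head_units[-1] != 1 and self.image_head_units[-1] != 4:
            raise ValueError("image head must end in 1 (image-only) or 4 (mixed) units")
        if self.clim_branch_units[-1] != self.fusion_units[0] - self.image_head_units[-1] and (
            self.image_head_units[-1] == 4
        ):
            raise ValueError("fusion input width must equal image + climate branch widths")


def _dense_stack(units: Sequence[int], n_in: int, rng: np.random.Generator) -> list[nn.Layer]:
    """Dense layers with ReLU between; the final layer is linear."""
    layers: list[nn.Layer] = []
    for i, width in enumerate(units):
        last = i == len(units) - 1
        layers.append(nn.Dense(n_in, width, rng, relu_fan=not last))
        if not last:
            layers.append(nn.ReLU())
        n_in = width
    return layers


class _TinyBackbone(nn.Layer):
    """Compact CPU backbone: 4× average pool, two 3×3 conv/ReLU blocks, GAP.

    The pooled raw channel means are concatenated to the convolutional
    features, so first-order image statistics (foreground coverage, colour
    intensity) reach the regression head directly while the convolutions
    learn texture/shape cues.
    """

    N_FEATURES = 19  # 16 conv channels + 3 raw channel means

    def __init__(self, rng: np.random.Generator):
        self.pool = nn.AvgPool2D(4)
        self.conv1 = nn.Conv2D(3, 16, 3, rng)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2D(16, 16, 3, rng)
        self.relu2 = nn.ReLU()
        self.gap = nn.GlobalAvgPool()
        self.raw_gap = nn.GlobalAvgPool()

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def grads(self):
        return self.conv1.grads() + self.conv2.grads()

    def forward(self, x):
        xp = self.pool.forward(x)
        h = self.relu2.forward(self.conv2.forward(self.relu1.forward(self.conv1.forward(xp))))
        return np.concatenate([self.gap.forward(h), self.raw_gap.forward(xp)], axis=1)

    def backward(self, grad):
        g_conv, g_raw = grad[:, :16], grad[:, 16:]
        gh = self.gap.backward(g_conv)
        gxp = self.conv1.backward(
            self.relu1.backward(self.conv2.backward(self.relu2.backward(gh)))
        )
        gxp = gxp + self.raw_gap.backward(g_raw)
        return self.pool.backward(gxp)


def _tiny_backbone(rng: np.random.Generator) -> tuple[list[nn.Layer], int]:
    backbone = _TinyBackbone(rng)
    return [backbone], backbone.N_FEATURES


def build_model(cfg: TraitModelConfig, head: RegressorHeadSpec | None = None) -> nn.MixedNetwork:
    """Construct the (image-only or mixed) regressor described by ``cfg``.

    Returns a network whose ``forward`` maps a batch of
    (image_size, image_size, 3) images in [0, 1] — plus, for mixed models,
    a (batch, 6) matrix of normalized climate predictors — to one scalar
    prediction per sample. The parameter count is logged.
    """
    if cfg.backbone not in BACKBONES:
        raise ValueError(f"unknown backbone {cfg.backbone!r}; valid options: {list(BACKBONES)}")
    if cfg.backbone in _UNAVAILABLE_BACKBONES:
        raise BackboneUnavailableError(
            f"backbone {cfg.backbone!r} requires a GPU deep-learning framework and "
            "pretrained weights, which this package does not ship; use 'tiny_test_cnn'"
        )
    head = head or RegressorHeadSpec()
    rng = np.random.default_rng(cfg.seed)
    backbone_layers, n_feats = _tiny_backbone(rng)
    if not cfg.mixed_data:
        image_branch = nn.Sequential(backbone_layers)
        fusion = nn.Sequential(_dense_stack(head.image_head_units, n_feats, rng))
        net = nn.MixedNetwork(image_branch, None, fusion)
    else:
        image_units = head.image_head_units if head.image_head_units[-1] == 4 else (512, 4)
        image_branch = nn.Sequential(backbone_layers + _dense_stack(image_units, n_feats, rng))
        clim_branch = nn.Sequential(_dense_stack(head.clim_branch_units, len(BIOCLIM_VARS), rng))
        fusion_in = image_units[-1] + head.clim_branch_units[-1]
        fusion = nn.Sequential(_dense_stack(head.fusion_units, fusion_in, rng))
        net = nn.MixedNetwork(image_branch, clim_branch, fusion)
    # start the output at the midpoint of the normalized target range so the
    # first optimizer steps are not dominated by a large constant offset
    net.fusion.layers[-1].b[:] = 0.5
    logger.info("built %s model (%d parameters)", cfg.backbone, net.n_params())
    return net


# ---------------------------------------------------------------------------
# image pipeline


def preprocess_image(img, image_size: int) -> np.ndarray:
    """Center-crop to square, resize to ``image_size``², scale to [0, 1].

    ``img`` may be a path to a JPEG/PNG or an HWC uint8/float array. Images
    smaller than the target are upsampled with a warning.
    """
    if isinstance(img, (str, Path)):
        try:
            pil = Image.open(img).convert("RGB")
        except OSError as exc:
            raise OSError(f"unreadable image file: {img}") from exc
    else:
        arr = np.asarray(img)
        if arr.dtype != np.uint8:
            arr = (np.clip(arr, 0.0, 1.0) * 255).round().astype(np.uint8)
        pil = Image.fromarray(arr, mode="RGB")
    w, h = pil.size
    side = min(w, h)
    if side < image_size:
        warnings.warn(
            f"image {getattr(img, 'name', '')} shorter side {side}px < target "
            f"{image_size}px; upsampling",
            RuntimeWarning,
            stacklevel=2,
        )
    left = (w - side) // 2
    top = (h - side) // 2
    pil = pil.crop((left, top, left + side, top + side))
    pil = pil.resize((image_size, image_size), Image.BILINEAR)
    return np.asarray(pil, dtype=float) / 255.0


def augment_image(
    img: np.ndarray,
    rng: np.random.Generator | None = None,
    *,
    hflip: bool | None = None,
    vflip: bool | None = None,
    contrast: float | None = None,
    saturation: float | None = None,
    brightness: float | None = None,
    factor_range: tuple[float, float] = (0.9, 1.1),
) -> np.ndarray:
    """Random flips plus contrast/saturation/brightness jitter, clipped to [0, 1].

    Flips are independent coin flips; each photometric factor is drawn
    uniformly from ``factor_range``. Contrast scales deviations about the
    image mean, saturation scales chroma about per-pixel luma (Rec. 601
    weights), brightness multiplies all channels. Explicit keyword values
    override the random draws (all factors 1.0 and no flips is the
    identity).
    """
    x = np.asarray(img, dtype=float)
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError("expected an HxWx3 array")
    if rng is None and None in (hflip, vflip, contrast, saturation, brightness):
        raise ValueError("provide an rng or all augmentation parameters explicitly")
    lo, hi = factor_range
    if hflip is None:
        hflip = bool(rng.random() < 0.5)
    if vflip is None:
        vflip = bool(rng.random() < 0.5)
    if contrast is None:
        contrast = float(rng.uniform(lo, hi))
    if saturation is None:
        saturation = float(rng.uniform(lo, hi))
    if brightness is None:
        brightness = float(rng.uniform(lo, hi))
    if hflip:
        x = x[:, ::-1, :]
    if vflip:
        x = x[::-1, :, :]
    if contrast != 1.0:
        mean = x.mean()
        x = mean + (x - mean) * contrast
    if saturation != 1.0:
        luma = x @ np.array([0.299, 0.587, 0.114])
        x = luma[..., None] + (x - luma[..., None]) * saturation
    if brightness != 1.0:
        x = x * brightness
    return np.clip(x, 0.0, 1.0)


def load_images(
    obs: Sequence[LinkedObservation], image_size: int, base_dir: str | Path | None = None
) -> np.ndarray:
    """Preprocess every observation's image into one (N, S, S, 3) array."""
    base = Path(base_dir) if base_dir is not None else None
    out = np.empty((len(obs), image_size, image_size, 3))
    for i, o in enumerate(obs):
        path = Path(o.image_ref)
        if base is not None and not path.is_absolute():
            path = base / path
        out[i] = preprocess_image(path, image_size)
    return out


def climate_matrix(
    obs: Sequence[LinkedObservation], params: dict[str, NormalizationParams]
) -> np.ndarray:
    """(N, 6) matrix of bioclim predictors, each min–max scaled by its train extrema."""
    rows = []
    for o in obs:
        if o.bioclim is None:
            raise ValueError(f"observation {o.record_id!r} has no bioclim vector")
        raw = o.bioclim.as_array()
        rows.append([normalize(v, params[name]) for v, name in zip(raw, BIOCLIM_VARS)])
    return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainingHistory:
    train_mae: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    best_epoch: int | None = None

    @property
    def n_epochs(self) -> int:
        return len(self.train_mae)


def train(
    model: nn.MixedNetwork,
    split: DatasetSplit,
    cfg: TraitModelConfig,
    target_params: NormalizationParams,
    plasticity: bool = False,
    bioclim_params: dict[str, NormalizationParams] | None = None,
    base_dir: str | Path | None = None,
    images: dict[str, np.ndarray] | None = None,
) -> TrainingHistory:
    """Fit the model on the training split with early stopping on validation MAE.

    Minimizes MSE over batches of augmented images (and normalized climate
    vectors for mixed models). With ``plasticity`` each presentation of an
    observation draws a fresh target from the truncated species
    distribution; validation always uses the deterministic species-mean
    targets, un-augmented. Training stops once the validation MAE has not
    improved for ``cfg.patience`` epochs (or at ``cfg.max_epochs``) and the
    best-epoch weights are restored. ``images`` may supply preloaded
    record_id → array data to skip disk I/O.
    """
    if not split.validation:
        raise ValueError("validation set is empty")
    if cfg.max_epochs == 0:
        return TrainingHistory()

    def arrays_for(part: list[LinkedObservation]) -> tuple[np.ndarray, np.ndarray | None]:
        if images is not None:
            imgs = np.stack([images[o.record_id] for o in part])
        else:
            imgs = load_images(part, cfg.image_size, base_dir)
        clim = None
        if model.mixed:
            if bioclim_params is None:
                raise ValueError("mixed model training requires bioclim_params")
            clim = climate_matrix(part, bioclim_params)
        return imgs, clim

    train_imgs, train_clim = arrays_for(split.train)
    val_imgs, val_clim = arrays_for(split.validation)
    fixed_targets = normalized_targets(split.train, target_params)
    val_targets = normalized_targets(split.validation, target_params)

    rng = np.random.default_rng(cfg.seed)
    opt = nn.RMSprop(model, lr=cfg.lr, decay=cfg.lr_decay)
    history = TrainingHistory()
    best_weights = model.get_weights()
    best_val = np.inf
    stale = 0
    n = len(split.train)

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        abs_err_sum = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = train_imgs[idx]
            if cfg.augment:
                batch = np.stack([augment_image(im, rng) for im in batch])
            if plasticity:
                targets = plasticity_targets([split.train[i] for i in idx], target_params, rng)
            else:
                targets = fixed_targets[idx]
            clim = None if train_clim is None else train_clim[idx]
            model.zero_grad()
            pred = model.forward(batch, clim)
            _, grad = nn.mse_loss(pred, targets)
            model.backward(grad)
            opt.update()
            abs_err_sum += float(np.abs(pred[:, 0] - targets).sum())
        train_mae = abs_err_sum / n
        val_pred = model.predict(val_imgs, val_clim)
        val_mae = float(np.mean(np.abs(val_pred - val_targets)))
        history.train_mae.append(train_mae)
        history.val_mae.append(val_mae)
        logger.info("epoch %d: train MAE %.4f, val MAE %.4f", epoch + 1, train_mae, val_mae)
        if val_mae < best_val - 1e-12:
            best_val = val_mae
            best_weights = model.get_weights()
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                logger.info("early stop after epoch %d (patience %d)", epoch + 1, cfg.patience)
                break
    model.set_weights(best_weights)
    return history
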