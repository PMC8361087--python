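# Methods

This note documents the modelling choices in `phototrait`: what each
stage assumes, which knobs matter, what the synthetic corpus does and
does not emulate, and where the design was genuinely open.

## Weak labels and data preparation

The central assumption is weak supervision: an individual photograph is
labelled with its **species'** trait statistics, not a measurement of
the photographed individual. The label noise this introduces is
irreducible at training time; the per-species image cap (default 8,
configurable per trait) exists so the network cannot circumvent it by
memorising species-specific appearance.

**Trait ingestion.** Trait tables are assumed to be in standardized
units per trait. Outliers are removed by a pooled z-score rule: records
deviating from the pooled mean by more than `z_max` (default 4) pooled
sample standard deviations are dropped, and the rule is **iterated to a
fixed point** because removing an extreme value shrinks the pooled SD
and can expose further extremes; iteration makes the filter idempotent,
which a single pass is not. An absolute-difference reading of the
threshold is unit-dependent and therefore not used, but `z_max` is
configurable. Species statistics use the sample (n−1) SD; a species with
one record has SD 0 and is excluded from target augmentation. Species
matching is exact after whitespace collapsing and case-folding — no
synonym resolution.

**Occurrence screening.** Records lose eligibility for missing or
out-of-bounds coordinates or a coordinate uncertainty *strictly greater*
than 100 km (the boundary value survives). Records with unknown
uncertainty are kept: occurrence exports frequently omit the field and
dropping them would discard most data; the counts are logged. Suspect
species names are handled by an optional user-supplied allow-list, since
no automated detection rule is defined here.

**Climate predictors.** Six predictors are sampled at each photo
location from rasters of BIO1, BIO4, BIO7, BIO12, BIO15 and the derived
BIO13−BIO14 (precipitation annual range). Sampling takes the value of
the cell containing the point — no interpolation — which is the natural
reading at 10-arc-minute resolution. Records hitting no-data cells
(e.g., off-land geolocations) are dropped.

**Targets.** Trait distributions are strongly right-skewed, so targets
are log10 species means. After linking, observations whose log-target
lies more than 3 SD from the dataset mean are trimmed; this runs once
per trait dataset *before* splitting so the trim cannot depend on the
split. Targets and each climate variable are then min–max scaled with
extrema of the **training split only**; validation/test values may fall
slightly outside [0, 1] and are not clipped. Fitting the scaler on any
superset that extends the training range provably changes the
parameters, which is what the leakage test asserts.

**Splits.** The test set takes round(0.1·N) records (an explicit count
may be supplied instead, to reproduce published splits whose test counts
are not exactly 10%); the remainder R is split 4:1 with validation =
floor(R/5). This floor convention reproduces the published
train/validation counts exactly for all six trait datasets.

## Target augmentation ("plasticity")

With σ<sub>s</sub> > 0, every presentation of an observation during
training draws a fresh target from 𝒩(μ<sub>s</sub>, σ<sub>s</sub>)
truncated to [μ<sub>s</sub>−σ<sub>s</sub>, μ<sub>s</sub>+σ<sub>s</sub>]
**in original trait units** (the scale on which μ and σ were computed),
then log-transforms, normalises and clips to [0, 1]. Sampling on the
original scale is a choice — the alternative (normalized scale) is a
one-line config away — made because the species statistics are defined
there. The symmetric truncation preserves the mean, which the tests
check by Monte Carlo. If μ−σ ≤ 0 the interval is floored at the smallest
positive float (with a warning) to keep the logarithm defined. A fresh
draw per presentation (rather than one frozen draw per record) parallels
image augmentation, which is also re-drawn per presentation. σ = 0
species degrade exactly — bit-exactly, asserted — to the unaugmented
setup. Validation targets are never augmented.

## Networks and training

Architecture follows the published head layout: image-only models use
global average pooling → dense 512 → dense 1; mixed models use an image
branch ending in 4 linear units, a climate branch 64 → 32 → 4, and a
fusion stack 8 → 8 → 4 → 1. Branch-final and output layers are linear,
all other dense layers ReLU. Loss is MSE; the optimizer is RMSprop
(lr 0.001, ρ 0.9) with inverse-time decay lr/(1 + 0.0001·step) — the
decay convention of the framework generation the published setup used.
Early stopping monitors validation MAE with patience (default 5) and
restores the best-epoch weights; the qualitative "stopped when
validation stopped improving" criterion needs an operational form and
patience-with-restore is the standard one.

Because no deep-learning framework is part of this package's
dependencies, the layers (valid-padding convolution via
`sliding_window_view`, pooling, dense) and their backward passes are
implemented in NumPy in `phototrait.nn`, in float64, seeded and
single-threaded, so training runs are bit-reproducible. Backward
correctness is verified against central-difference gradients in the test
suite. The working backbone is `tiny_test_cnn`: 4× average pooling, two
3×3 conv/ReLU blocks (16 channels), global average pooling, with the raw
pooled channel means concatenated to the conv features so first-order
image statistics (foreground coverage, colour intensity) reach the
regression head directly while the convolutions carry texture and shape.
The named large backbones (Inception-ResNet-v2, Xception, half-width
MobileNetV2) are accepted configuration values that raise an informative
error: they require GPU-scale frameworks and pretrained weights that are
not shipped.

Two initialization choices matter for stability of the narrow fusion
stack: ReLU-bound layers start with bias 0.05 (He weights otherwise),
and the output bias starts at 0.5, the midpoint of the normalized target
range. Without them, RMSprop's near-sign-magnitude early steps —
amplified by the large constant offset between a random-init output and
targets centred near 0.5 — can kill the 8-unit ReLU layers outright,
leaving a constant predictor. Biases are not constrained by the
published architecture description.

**Image pipeline.** Images are center-cropped to a square and resized
(bilinear) to the configured size — 512 px mirrors the published
configuration, 64 px is the desk-scale default — then scaled to [0, 1].
Augmentation applies independent 50% horizontal/vertical flips and
contrast, saturation and brightness factors drawn uniformly from
[0.9, 1.1], clipping back to [0, 1]. The photometric operations use the
common photographic definitions (contrast scales deviations about the
image mean; saturation scales chroma about Rec. 601 luma; brightness
multiplies channels), since only the operation names are specified.

## Evaluation

NMAE = 100·MAE/range(test targets) is computed on the normalized target
scale by default (the training scale; an original-units option exists)
and is invariant to joint affine rescalings of predictions and targets.
R² is the squared Pearson correlation of predictions versus targets —
identical to the R² of the simple linear fit — so a constant offset does
not hurt it; constant predictions report R² = 0. Ensembles are
element-wise means; Jensen's inequality guarantees ensemble MSE ≤ mean
member MSE, which is asserted per batch (the analogous MAE bound is
false in general and not asserted). Cross-validation partitions the
shuffled data into k disjoint test folds and re-randomises the 4:1
train/validation split per fold. The robustness analysis groups absolute
errors by annotation category (growth form, image quality, image-target
distance) and applies a Kruskal–Wallis rank test at α = 0.05; the
particular k-sample rank test is a swappable choice, with all errors
tied the p-value is defined as 1.

## Trait maps

Point predictions in original units are interpolated by inverse-distance
weighting evaluated at cell centers: value = Σ wᵢvᵢ/Σ wᵢ with
wᵢ = dᵢ^(−2) and dᵢ the haversine distance (Earth radius 6371 km);
planar distances would be wrong at high latitudes. A cell center
coinciding with observations (within 10⁻⁶ km) takes their mean exactly.
All points contribute (no k-nearest cutoff); power and cutoffs are
configurable since neither is pinned down. Cells farther than
`buffer_km` (default 100, same metric) from every observation are
masked, as are cells off the optional land-mask raster; the unmasked
count is monotone in the buffer. Cell-center evaluation was chosen over
averaging a subgrid of evaluations because it is deterministic and
directly testable; the quantile-range map (q.9 − q.1, linear
interpolation between order statistics) is computed from the raw point
values per cell by default, with an interpolated-values mode as the
alternative reading. Raster comparison resamples the second grid
bilinearly onto the first and reports Pearson r with its two-sided
p-value over jointly valid cells; no spatial-autocorrelation correction
is applied. log10 display of LA/SM maps affects rendering only. Rasters
are stored as ESRI ASCII grids or TIFF with world-file sidecars, both on
regular WGS84 cell-edge-registered grids.

## Synthetic corpus

The generator makes the core hypothesis — traits inferable from visible
leaf features — literally true so it can be tested. Each species gets a
characteristic leaf-disc area fraction a ∈ (0.08, 0.45), greenness
g ∈ (0.3, 0.9) and a home range (a box of ±5° around a random center on
a rectangular landmass), emulating climatic niches; each image renders
elliptical "leaves" on a textured brown background with per-image jitter
of a and g, and the latent trait is

    trait = base + c_area·a + c_green·g + c_climate·clim + ε

with `a` the **exact painted pixel fraction** (placement tolerates
overlap rather than dropping discs, so the image always shows the area
the trait was computed from), `clim` the normalized synthetic
annual-mean-temperature at the image's location, and ε Gaussian noise.
Trait tables contain per-species records drawn around the species' mean
latent trait with spread `sd_frac`·μ, so ingestion recovers means
consistent with the imagery and SDs that activate target augmentation.
Climate layers are smooth latitude/longitude gradients with no-data over
the ocean. Defaults: 40 species, 2–8 images each, 64 px images, 3 discs,
c_area 2.0, c_green 0.5, c_climate 0, σ_noise 0.02, sd_frac 0.15.

What the corpus does **not** emulate: photographic realism, observation
bias of citizen scientists, taxonomic structure, real coastlines, or
label errors from misidentification. Passing tests therefore demonstrate
that the pipeline's machinery is correct and that the training recovers
signal that is present; they say nothing about how much signal real
photographs carry.

The end-to-end experiments use 125 species × 2–6 images (~500 images) at
64 px with the compact backbone and at most 10 epochs — sizes chosen so
a full experiment runs in seconds on one CPU while leaving a clear
margin between the informative case (R² ≈ 0.6–0.8, near the weak-label
oracle ceiling computed from the latent traits), the negative control
(R² below the 95% null bound), and the climate-fusion gain (>0.25 R²
when climate carries about half the trait variance).

## Known limitations

* The compact backbone is a functional stand-in for the published
  GPU-scale architectures; absolute accuracies on real photographs are
  out of reach at this scale and are not claimed.
* IDW over all points is O(points × cells); global 0.5° grids with many
  thousands of points are feasible but not fast.
* The truncated-normal floor for μ − σ ≤ 0 distorts the draw
  distribution for such species (it warns); a multiplicative
  (log-normal) augmentation would be the principled alternative.
* Grid registration assumes north-up regular lat/lon cells; projected
  rasters are out of scope.
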