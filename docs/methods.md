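# Methods

`blscreen` implements a slide-screening pipeline for distinguishing an
aggressive, highly cellular lymphoid malignancy (Burkitt-lymphoma-like
tissue) from benign lymphoid tissue (tonsil-like controls) on H&E-stained
whole-slide images, using weak slide-level labels only.  This note records
the models, the parameters that matter, and the design choices made where
the design was genuinely open.

## Pipeline model

A slide is never classified as a whole image.  It is decomposed into
fixed-size tiles at several nominal magnifications (5x/10x/20x/40x, i.e.
2/1/0.5/0.25 µm per pixel), the tiles are quality-controlled and
color-normalized, and the surviving tiles form a *bag* under the
multiple-instance learning (MIL) assumption: the bag carries the slide's
diagnosis, a bag is positive if at least one instance is, and no tile-level
annotation exists.  Six independently trained bag classifiers vote; the
ensemble decision is the majority class when more than half the votes
agree, and an explicit *indecision* (abstention) when the vote splits
exactly — abstaining slides are flagged for priority human review rather
than guessed at.

### Tiling

Tiles are laid on a regular grid with stride `tile_size − overlap`
(defaults 450 px and 20 px; the overlap imitates a pathologist panning with
overlap between fields of view).  Coordinates are 0-based, half-open,
`x` = column.  Partial tiles at the right/bottom edge are dropped: the QC
statistics and the networks require fixed-size inputs, and padding would
manufacture artificial background.  Note one consequence of overlap: a
pixel inside an overlap strip legitimately belongs to two tiles.
Magnification levels are derived by repeated 2× area-average downsampling
of the finest available raster; tiles from all levels are pooled into one
bag per slide.

### Tile quality control

Four filters run in a fixed order and short-circuit at the first failure,
so each rejected tile is attributed to exactly one stage:

1. **background** — pooled standard deviation of all RGB values;
   near-blank glass has almost none.  Default floor: 8.0 (8-bit units).
2. **pen** — fraction of pixels inside any of three HSV masks for
   annotation ink: green (hue 80–160°), blue (hue 200–260°) at saturation
   ≥ 0.25, and gray (saturation ≤ 0.12, value 0.2–0.8).  Default ceiling:
   0.05.
3. **purple/pink** — ratio of hematoxylin-hued (250–310°) to eosin-hued
   (310–360°) pixel counts among pixels with saturation ≥ 0.15.  Low
   ratios indicate scant cellularity, fibrosis, or fold/tear artifacts.
   Zero pink with nonzero purple passes (ratio +∞); zero in both bands
   means no stain evidence and fails.  Default floor: 0.3.
4. **otsu** — ITU-R BT.601 luma, complemented so tissue is the high class,
   thresholded by Otsu (exhaustive between-class-variance argmax over the
   256-bin histogram, ties to the lowest threshold); the fraction strictly
   above threshold estimates tissue coverage.  Default floor: 0.10.

All constants are configuration, not contract: the filter *structure* is
the fixed part.  The numeric defaults were calibrated once against the
synthetic tile generator and are the package's own choices.

### Stain normalization

Per-channel moment matching in YCbCr (one luma + two chroma channels):
`out = (in − µ_tile)/σ_tile · σ_ref + µ_ref`, then back to 8-bit RGB.
A *linear* opponent space was chosen deliberately over CIELAB/lαβ: in a
channel-wise linear space the transform is exactly invariant to global
brightness offsets and per-channel affine distortions — two tiles differing
only by such a shift normalize bit-identically, which is the property that
makes tiles from different scanners comparable.  Gamut clipping is
re-entrant: after clipping out-of-gamut pixels the moments are re-matched
until the clip/match cycle reaches a fixed point (≤ 8 iterations in
practice, convergence tolerance 0.25/255), which makes the operation
idempotent up to 8-bit quantization.  Every affine pass has exactly the
reference moments before clipping.  The default reference is computed on
demand from the package's canonical synthetic clean-tile set (seeds 0–4
per class) and versioned; stain-vector deconvolution (Macenko-style) could
replace the transform behind the same signatures.

### MIL models and training

Each of the six ensemble variants is a small convolutional network written
in numpy with explicit backprop: three 3×3-conv + ReLU + 2×2-maxpool
blocks, global average pooling to a per-instance embedding, then either

* **plain pooling** — a per-instance softmax classifier whose class
  probabilities are averaged over the bag (mean rather than max pooling:
  smoother gradients at the small per-step sample sizes used here; max is
  the natural alternative), or
* **gated attention pooling** — per-instance score
  `w·(tanh(hV) ⊙ σ(hU))`, softmax over instances, attention-weighted sum
  of embeddings, then a softmax classifier.  The *attention head size* is
  the hidden width of the scoring layer (grid: 10/50 for the
  efficientnet-like preset, 16/64 for the others).

The backbone presets (`resnet50-like`, `efficientnet-like`,
`googlenet-like`, `tiny-cnn`) differ in channel widths (12/24/48, 6/12/24,
10/20/40, 8/16/32) and are stand-ins at matching capacity ordering for the
full-size pretrained families; backbones are pluggable behind
`MILNet`, and everything downstream (sampling, early stopping,
checkpointing, consensus) is architecture-agnostic.

Training protocol: two-class cross-entropy on the bag output; Adam at
learning rate 0.001; per epoch each bag contributes a *fresh* uniform
without-replacement sample of `sample_size` instances (resampled every
epoch, so over training a model sees most of each bag), batched
`batch_size` bags per optimizer step; inputs resized to
`input_size_px` and standardized with channel means (0.485, 0.456, 0.406)
and stds (0.229, 0.224, 0.225).  Early stopping halts training when the
running minimum of the validation loss has not improved by more than 1e-6
for 5 consecutive epochs, with a hard cap of 20 epochs; the checkpoint is
the best-validation-loss epoch.  Validation and inference always use all
instances of a bag.

Splitting is at slide level (no slide's tiles ever straddle partitions) in
a 6:2:2 train/val/test ratio via seeded shuffle and largest-remainder
rounding, stratified by label — with cohorts of this size an unstratified
split can produce a single-class partition, which would make training or
evaluation degenerate.

### Ensemble and metrics

Each model votes by thresholding its bag probability at 0.5 (votes are
hard: "at least 4 of 6 models converged" is then exactly confidence
> 50%).  Confidence = majority count / N.  The three-way report
(percent correct / indecision / incorrect) uses largest-remainder rounding
to integers summing to 100; remainder ties are resolved in favor of
incorrect, then indecision, then correct, so rounding never understates
the error column.  Indecision slides are excluded from the
accuracy/precision/recall denominators and accounted separately.
Accuracy, precision, recall and F1 come from the confusion matrix, with
undefined ratios reported as absent rather than 0; AUC is the rank-based
Mann–Whitney statistic with ties counted ½.  When an ensemble AUC is
reported it scores with the mean of per-model probabilities (an audit
metric; decisions are vote-based).

## Synthetic cohort

Real cohorts of this kind are private clinical material, so the package
ships a generator whose pseudo-slides reproduce the *structure* the
pipeline depends on, not histology itself:

* **class signal** — purple (hue 270°) elliptical nucleus blobs with
  jittered radius/eccentricity on a pink (hue 330°) stromal field; the
  positive class covers 55% of tissue area with nuclei versus 25% for
  controls, a separable density signal mirroring the high cellularity of
  the malignancy.  Blobs are stamped until measured coverage reaches the
  target, which also pins the purple:pink ratio of clean control tiles
  safely above the QC floor (0.25/0.75 ≈ 0.33 > 0.3).
* **contamination** — near-constant glass rectangles (blank), thick
  meandering pen strokes in green/blue/gray, and low-tissue tiles with a
  small stained island on glass; defaults per slide are 10% blank and 3%
  pen area.
* **cohort shape** — labeled positive/negative slides with per-slide seeds
  derived from one base seed; the demo cohort is 20+20 slides of
  320×320 px rendered at "20x" with a derived "10x" level, tiled at 64 px
  with 8 px overlap — a deliberately desk-scale geometry chosen so a full
  six-model run remains a few minutes of CPU; the tiling/QC/training code
  is size-agnostic.

What the generator does **not** emulate: nuclear texture and chromatin,
starry-sky macrophage holes (hook present, off by default), scanner noise,
compression artifacts, focus blur, or any within-class biological
variability beyond seed jitter.  Passing tests therefore demonstrate that
the pipeline's machinery — filtering, normalization, bag construction,
optimization, consensus — recovers a known separable signal end-to-end;
they say nothing about diagnostic performance on real tissue, for which
the synthetic percentages should be read qualitatively, not as clinical
estimates.

## Numerical choices and degenerate inputs

* Otsu ties resolve to the lowest maximizing threshold; constant tiles
  (one-bin histogram) are defined to fail with tissue fraction 0.
* A constant channel during normalization (σ undefined) is shifted to the
  reference mean and logged rather than raised.
* `sample_instances` with a request ≥ bag size returns all instances,
  never duplicates.
* Largest-remainder rounding is used everywhere an integer partition of a
  ratio is needed (split counts, report percentages).
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; identical configuration and seeds reproduce
  histories, checkpoints and predictions bit-for-bit.

## Known limitations

* No out-of-core WSI reading: slides enter as in-memory rasters or tile
  directories; vendor formats (SVS/MRXS) and pyramidal-TIFF streaming are
  out of scope.
* The numpy networks are CPU-bound and desk-scale by design; they share
  the training contract, not the capacity, of large pretrained backbones.
* Probabilities are not calibrated; the vote threshold (0.5) and the
  abstention rule are fixed, not cost-sensitive.
* Blur/focus QC and cautery/crush artifacts are not detected (such slides
  are assumed excluded upstream).
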