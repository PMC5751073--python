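# Methods

## The problem and the pipeline

The clover fraction of a mixed clover-grass sward drives its nitrogen
management, but measuring it destructively (harvest, separate species by
hand, dry, weigh) is impractical at field scale. `cloversim` implements a
two-stage, image-based estimate: (i) semantic segmentation of top-down
RGB canopy images into soil, clover, grass, and weed pixels, with the
segmenter trained purely on *simulated* labeled images; (ii) a linear
coupling from the clover fraction of the segmented canopy to the clover
fraction of the dry matter, fitted on plots where both an image and a
species-separated harvest exist.

## Plant-cutout library (`flora`)

Real pipelines hand-segment a few hundred single plants from field
photographs. The package instead draws procedural cutouts at a nominal
ground sample distance of 5 px/mm (midpoint of the 4–6 px/mm typical of
cart-mounted cameras):

- **Clover**: 3–4 elliptical leaflets (default radius 4 mm) on short
  petiole stubs radiating from a centre, each leaflet carrying the pale
  crescent watermark characteristic of *Trifolium*; optionally a pale
  pink-white flower head. Leaflets are deliberately disjoint connected
  components, as leaves of a rosette seen from above mostly are.
- **Grass**: 3–6 thin, curved, tapering blades (default length 20 mm,
  width ≤ length/10) fanning from a base point.
- **Weeds**: lobed rosettes with species-specific leaf length, width, and
  lobing (dandelion long and jagged, thistle broad and spiky with lower
  saturation, shepherd's purse small).

All hue ranges are green-dominant with per-structure jitter, and a
multiplicative smoothed-noise texture is applied before cropping to the
alpha support. Defaults live in `StyleParams`; they were chosen so the
classes are separable by simple shape/color statistics (grass fills less
than ~25% of its bounding box, clover more), which the property suite
asserts. The generator is deterministic per seed.

A loader ingests user-supplied cutouts named
`<species>_<flower|noflower>_<id>.png`, skipping unreadable files with a
warning and failing only when nothing valid remains.
`REFERENCE_SAMPLE_COUNTS` documents the per-species inventory of the
reference field library this generator mirrors (55 grass, 117 clover,
14 dandelion, 5 thistle, 4 shepherd's purse; 195 total); `subsample_library`
implements the random 25% reduction used in sensitivity studies
(round-half-up, so 195 → 49).

## Field simulation (`simulate`)

A field composition is one point of a factorial grid — weed ratio
∈ {0, 1/16, 1/8}, a density level, flowering on/off — plus a fresh
clover/grass ratio drawn uniformly on [0, 1] per image and a ±10%
multiplicative jitter on density. Default density levels are
(10, 1500, 6000, 15000) plants/m², spanning nearly bare soil to complete
coverage *for the default plant geometry*; density levels are config
values because "complete coverage" depends on cutout size.

Rendering places `round(density × canvas area)` plants at uniform random
positions (overhang is clipped). Each instance is augmented independently:
rotation from the discrete uniform {0°,…,359°} (quarter-turns exact,
otherwise bilinear), scale and saturation uniform on [0.75, 1.25], with
saturation applied on the S channel of an HSV decomposition and the alpha
mask transformed identically to the color channels. Before compositing,
the instance's blurred alpha mask (Gaussian σ = 0.2 × its mean
bounding-box side; darkening to 0.65 at full mask intensity, linearly
attenuated with mask value) multiplies the composite underneath, so
shadows accumulate iteratively and broad leaves shade more than thin
blades. Labels are overwritten in placement order: each pixel carries the
class of the topmost plant whose (transformed) alpha support covers it,
soil elsewhere. The placement list (sample index, position, rotation,
scale, saturation) fully determines the label map, which the test suite
verifies against an independent z-order replay.

Soil is a procedural brown texture (smoothed Gaussian mottling plus fine
grain); a user-supplied soil raster can be dropped in by compositing onto
it directly.

Corpora derive one child seed per image from the master seed by a
counter-based affine map modulo 2³¹, so generation is order-independent
and bit-reproducible; the composition grid is cycled so every grid point
is visited when the corpus is at least as large as the grid. A
multi-scale step resamples every pair to 100/75/50/25% (bilinear images,
nearest-neighbour labels), quadrupling the corpus, as is standard for
making segmenters robust to capture height.

## Segmenters (`segment`)

**Morphological baseline.** Vegetation is split from soil by the excess
green index (ExG = 2g − r − b on chromaticity coordinates) with a
threshold; within vegetation, a smoothed Sobel edge-density map and a
disk-structuring-element opening separate broad, low-edge blobs (clover)
from thin or high-edge structure (grass); blobs above an area threshold
are reassigned to weed. Parameters are config values with a small
grid-tuning utility (`tune_morphological`), since classical methods need
per-dataset tuning. Scores are hard one-hot maps.

**Trainable pixel classifier.** A random forest over 12 per-pixel
features (RGB, HSV, ExG, Sobel magnitude, window mean/std of intensity,
Gaussian-smoothed intensity and ExG) with a per-class pixel sampling
budget. This is a deliberate desk-scale stand-in for a fully
convolutional network: it honours the same contract (train on simulated
pairs, emit normalized per-pixel score vectors, serialize to one file
with a JSON header) behind a pluggable interface, so a true FCN backend
can be swapped in. The FCN-8s geometry itself is encoded in the metrics
module for receptive-field arithmetic. Training is deterministic per
seed; classes absent from the training pairs are scored zero with a
warning. Its local features cannot use long-range context, so heavily
occluded or shadowed canopies are harder for it than for a deep model —
accuracy *orderings* on simulated data transfer, absolute accuracies on
real fields do not.

**Score → class.** `argmax_classify` breaks exact ties to the lowest
class index (soil < clover < grass < weed). `threshold_classify` accepts
a vegetation class only where its score *strictly* exceeds its per-class
threshold (defaults 0.95 clover, 0.8 weed, 0.3 grass — precision-first
for clover, recall-first for grass); among passing classes the highest
score wins, with exact ties resolved by threshold stringency
(clover < weed < grass); pixels passing nothing fall back to soil when
soil holds the argmax and to *unidentified* otherwise. With all-zero
thresholds and no soil mass this reduces exactly to vegetation argmax,
and lowering one threshold can only grow that class — both are property
tests. Strictness at the boundary and the tie policies are conventions;
one had to be picked and these degenerate cleanly.

## Metrics (`metrics`)

Confusion tables are accumulated over an evaluated class set; pixels
whose *truth* is unidentified are excluded entirely, while
predicted-unidentified pixels are tallied in a separate rejected column:
they count as wrong for pixel accuracy (conservative) but never enter
IoU, and the classified fraction is reported as `coverage`, since
thresholded segmentation deliberately trades coverage for stability.
Mean IoU averages only classes present in the ground truth of the
evaluated set (the convention differs across the literature, so it is
fixed and documented here). Evaluation of bordered images should segment
full frames and `center_crop` afterwards, because context thins near
borders.

Receptive-field arithmetic uses the standard recursion
`rf ← rf + (k − 1)·jump; jump ← jump·stride` through an ordered layer
stack; the bundled FCN-8s stack (13 VGG16 3×3 stride-1 convolutions,
2×2 stride-2 pools after layers 2, 4, 7, 10, 13, fc6 as 7×7, fc7 and
score as 1×1) yields a 404 px receptive-field side and effective stride
32 at the score layer, and the five-pool downscale factor is 2⁵ = 32.
The arithmetic is cross-checked against brute-force dependency tracing
on 1-D toy stacks.

## Composition coupling (`composition`)

Both fractions put weeds in the vegetation denominator (they are
harvested and segmented as vegetation); a documented `include_weeds`
toggle exists. White and red clover merge into the single clover class of
the segmentation. The regression direction is DM fraction on pixel
fraction — the prediction task — by ordinary least squares;
`residual_sd = sqrt(RSS/(n−2))`, and prediction intervals are the
standard OLS form `s·sqrt(1 + 1/n + (x−x̄)²/Sxx)` with a Student-t
quantile, clipped to [0, 1] alongside the point estimate. Records with
undefined fractions (zero vegetation mass or pixels) are excluded and
counted, never imputed.

The synthetic sample-pair generator emulates a field campaign: vegetation
pixel totals uniform on [50k, 200k], canopy fraction drawn (uniform by
default) and realized as an exact count ratio, DM fraction = linear
response + Gaussian noise (default sd 0.078 on the fraction scale, the
residual spread typical of canopy-based DM estimation) clipped to [0, 1],
and dry masses back-constructed from a uniform total yield of 20–200 g
per 0.25 m² patch with an 80/20 white/red clover split and a 5% weed DM
share. It reproduces its generating fractions exactly, which makes exact
round-trip fits possible in tests. What it does *not* model: occlusion
bias (canopy unrepresentative of biomass in mixed swards), out-of-focus
outliers, or site-to-site offsets — so passing calibration tests shows
the estimator is self-consistent, not that real fields obey the identity
line.

## Problem sizes and numerical choices

The test and acceptance suites run the full pipeline at reduced scale —
canvases of 96–256 px (≈ 2–5 cm of sward at 5 px/mm), corpora of 10–25
images, forests of 10–60 trees — chosen as the smallest sizes at which
the asserted properties are stable across seeds. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; score
normalization tolerates 10⁻⁶; augmented rasters are re-quantized to
uint8, so identity augmentation is bit-exact and quarter-turn rotations
conserve alpha mass exactly.

## Known limitations

- Procedural cutouts are morphological cartoons; no attempt is made to
  match the statistics of hand-segmented field plants, and simulated
  accuracies do not transfer to real imagery.
- The simulator omits lighting color temperature, blur, and sensor noise.
- The pixel classifier sees only local windows; it under-uses texture
  context compared to a convolutional network and is biased on
  prior-imbalanced scenes (its per-class sampling is balanced).
- The morphological baseline is faithful in spirit (color index + edges +
  morphology), not a line-by-line reimplementation of any published
  parameter set.
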