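# Methods

## Pipeline model

The package treats a canopy photograph as a mixture of two pixel
populations — green foliage and soil background — and summarizes the
foliage population by moment statistics (color) and second-order gray-level
co-occurrence statistics (texture) over a bank of 35 image transforms.
The underlying assumptions are: (a) the camera frames a single plot from
above so the plant pixels form the population of interest, not a sample
(hence population moment formulas with denominator N); (b) vegetation is
separable from soil in vegetation-index space; (c) all information in the
transforms derives from the three stretched channels, so the bank adds
redundancy, not new information — the feature-correlation summary
quantifies this.

## Pre-processing and segmentation

Contrast stretching maps each channel's 1st and 99th percentile (linear
interpolation between order statistics) to 0 and 255, saturating outside
and rounding half away from zero. A flat channel is returned unchanged —
the linear map is undefined and there is no contrast to stretch.
Percentile convention matters by less than one gray level on realistically
sized images; half-away rounding is pinned so results are bit-exact across
platforms.

Segmentation unions two masks: Otsu's threshold (256 histogram bins) on the
rescaled MExG − CIVE difference image, taking *strictly above* as plant
(vegetation is MExG-high and CIVE-low; the polarity is a package decision,
tested, since either side is defensible a priori), and a strict > 0.5 cut
on rescaled ExG (ties fall to background; a measure-zero choice on real
images). The difference image is not re-rescaled before Otsu — the method
is invariant to affine intensity maps. Components of ≤ 300 pixels
(inclusive) are removed using 8-connectivity (configurable); holes inside
plant regions are deliberately not filled. An image whose difference image
is constant, or whose mask cleans to empty, yields an invalid record rather
than partial output.

## Transform conventions

Decisions the color-space literature leaves open are pinned as follows and
exposed in `PipelineConfig`:

- **XYZ / L\*a\*b\***: 8-bit values are treated as nonlinear sRGB and
  inverse-companded before the D65, 2°-observer matrix
  (`assume_linear_rgb=False` default). This is the only defensible
  assumption for consumer webcam imagery.
- **HSI**: the Gonzalez & Woods arccos variant — I = (R+G+B)/3 scaled to
  [0, 1], S = 1 − 3·min(R,G,B)/(R+G+B), H in degrees [0, 360) with H = 0
  where undefined (achromatic pixels).
- **Y'CbCr**: ITU-R BT.601 full-range coefficients applied to the 8-bit
  values (not the studio-swing 16–235 range).
- Ratio indices are evaluated without special-casing: zero denominators
  produce NaN/±inf, and the sanitization step substitutes the raster's
  minimum (NaN, −inf) or maximum (+inf) finite value. ExG appears only in
  segmentation; rescaled to [0, 1] it is identical to NG, which is in the
  bank.

## Color and texture statistics

Color moments use population denominators. When σ = 0 the skewness and
kurtosis are 0/0 and reported as NaN — a numeric stand-in would fabricate
distribution shape where none is measurable; how to impute is the
modeller's decision, so the NA is propagated into the feature table (CSV
spelling `NA`).

For texture, each transform is rescaled **unmasked** to 0–255 and rounded
(half away from zero) before the mask is applied, so the quantization grid
reflects the whole image. Co-occurrence matrices are symmetric (each valid
pair counted in both orders) and NA-aware (a pair with a masked member is
skipped entirely). Entropy uses log base 2 with 0·log 0 = 0. MEA and VAR
use the single-margin forms, valid because the matrix is symmetric;
correlation is NaN when VAR = 0 (a single-gray-level region). The two
directions' statistics are averaged element-wise; 45°/135° directions and
coarser gray levels are available behind config but off by default — 256
levels retains the most information at acceptable cost. A transform with
no valid pair in some direction invalidates the whole image record,
keeping the 455-column schema rectangular.

## Covariates and table schema

Location is a user-supplied site code (1–4), never inferred from imagery.
Time is the plain calendar-day difference between planting and measuring
dates (no inclusive-endpoint adjustment). Column order is fixed:
140 color features (transform-major, `<name>_{mu,sigma,skew,kurt}`), 315
texture features (`<name>_{MP,MEA,VAR,COR,ASM,ENT,DIS,CON,IDM}`),
`location`, `time`. Invalid images are retained as flagged rows so
data-availability gaps remain auditable. Extraction is deterministic:
identical input and config give byte-identical records.

## Synthetic canopy generator

The generator emulates early-vegetative (V4/V5-stage) plot imagery: a soil
background with mean RGB (120, 95, 70) under per-pixel multiplicative
Gaussian noise, overlaid with clusters of three elliptical leaflets
(mimicking trifoliolate leaves) in jittered greens around (60, 150, 55),
with per-pixel additive noise and optional darkened shadow ellipses. The
truth mask is the union of rendered leaflet ellipses. Cluster centers are
inset from the frame border so no plant is clipped into a fragment smaller
than the 300-pixel cleaning size — real plants at this stage are far
larger, and the frame is centered on the plot; without the inset the truth
mask contains sliver components that no segmenter following the cleaning
rule could keep, which would measure the generator artifact rather than
the segmentation. The **easy** preset keeps foliage saturated and leaflet
sizes narrow (color jitter sd 10, size jitter 15%), representing favorable
acquisition; the **hard** preset desaturates leaves toward the soil hue,
widens both jitters and adds ~25% shadow cover as a diagnostic stress case
with no accuracy contract. Scenes default to 192 × 256 pixels — large
enough for hundreds of co-occurrence pairs per direction and multi-plant
layouts, small enough that full-pipeline tests run in milliseconds.
Everything derives from a `numpy` generator seeded from the scene seed;
identical (params, seed) gives bit-identical scenes. The generator reads
none of the segmentation thresholds, so segmentation accuracy measured
against its truth masks is not circular.

What passing tests on synthetic scenes do **not** show: robustness to
illumination gradients, color-cast or uncalibrated cameras, specular soil,
motion blur, or canopies past row closure. The hard preset probes shadow
and desaturation sensitivity only qualitatively.

## Evaluation statistics

R² is the 1 − SSE/SST form, not a squared correlation: on validation data
it is negative whenever predictions are worse than the observation mean,
and it is NaN for constant observations. Cohen's κ computes chance
agreement E from both marginals over the union of observed and predicted
labels; κ is NaN when E = 1 (both marginals on a single class). The
majority-class pathology — high accuracy, κ = 0 on imbalanced labels — is
covered by tests.

## Numerical choices and limitations

- Rounding anywhere an integer is produced: half away from zero.
- Otsu via 256-bin histogram; brute-force between-class-variance search is
  used as an independent oracle in tests, not in the implementation.
- Problem sizes in tests and the acceptance script (96 × 128 to 192 × 256
  scenes, 3–20 images, 200 oracle images ≤ 16 × 16) were chosen so the
  whole suite completes in seconds while still exercising every code path;
  feature counts and identities are size-invariant.
- The package extracts features only; model fitting (PLS, random forests,
  etc.), cross-validation and feature selection are downstream concerns —
  the CSV schema is designed to feed any such tool.
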