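# canopyfeat

Color and texture feature extraction from canopy RGB imagery, for plant
phenotyping and crop-trait prediction studies.

Early-season canopy photographs carry information about plant vigor, leaf
size and shape, and stand density. This package turns an 8-bit RGB canopy
image into a fixed 457-variable feature record suitable for downstream
regression or classification against end-season traits:

1. **Pre-processing** — per-channel contrast stretching that saturates the
   bottom and top 1% of intensities, then plant/soil segmentation combining
   three vegetation indices: excess green
   ExG = (2G−R−B)/(R+G+B), modified excess green
   MExG = 1.262G − 0.884R − 0.311B and the color index of vegetation
   extraction CIVE = 0.441R − 0.811G + 0.385B + 18.78745. The rescaled
   MExG−CIVE difference is thresholded with Otsu's method, rescaled ExG with
   a fixed 0.5 cut, and a pixel is plant if either mask accepts it;
   connected components of ≤ 300 pixels are removed as noise.
2. **Transform bank** — 35 rasters per image: the stretched R, G, B
   channels; CIE 1931 XYZ, CIE 1976 L\*a\*b\*, HSI and Y'CbCr channels; and
   20 RGB-band vegetation indices (NR, NG, NB, ExR, ExB, ExGR, GBD, RBD,
   RGD, GRR, GBR, NGRD, NGBD, MNGRD, VD, RGBVI, CI, CIVE, TGI, MExG).
   NaN/±inf produced by zero denominators are replaced by the raster's
   minimum/maximum finite value before masking.
3. **Color features** — per transform, the population moments over plant
   pixels: mean μ, standard deviation σ, skewness θ and kurtosis δ
   (denominator N, not N−1), giving 35 × 4 = 140 features.
4. **Texture features** — each transform is quantized to 256 gray levels,
   and NA-aware *symmetric* gray-level co-occurrence matrices
   p(i, j, d=1, θ) are accumulated for θ = 0° and 90°. Nine Haralick-style
   statistics per direction (maximum probability, mean, variance,
   correlation, angular second moment, entropy, dissimilarity, contrast,
   inverse difference moment) are averaged over the two directions, giving
   35 × 9 = 315 features.
5. **Covariates** — the plot Location code (1–4) and Time, the number of
   days from planting to measurement, complete the 455 + 2 = 457 columns.
   A 41-column reduced view (R/G/B features + covariates) is also exposed.

Prediction-evaluation statistics (RMSE, R² = 1 − SSE/SST, Bias, Accuracy,
Cohen's κ) and a synthetic canopy generator with ground-truth masks round
out the package, so every stage is testable without field data.

## Worked example

```python
import datetime as dt
import canopyfeat as cf

scene = cf.generate_scene(seed=1)                 # soil + foliage, known truth mask
meta = cf.ImageMetadata("demo", 1, dt.date(2016, 5, 20), dt.date(2016, 6, 21))
record = cf.extract_features(scene.image, meta)

print(len(cf.feature_columns()))                  # 457
print(record["G_mu"], record["G_ENT"])            # 192.0275 10.0638
```

`G_mu` is the mean stretched green intensity over plant pixels; `G_ENT` is
the direction-averaged co-occurrence entropy of the green channel (bits) —
larger values mean a more complex canopy texture. Segmenting the same kind
of scene and scoring against the rendered truth
(`examples/01_segment_canopy.py`) prints a mask IoU of 1.0000 at a plant
cover of 0.240; batch extraction over six scenes
(`examples/03_batch_and_correlation.py`) yields the 455 × 455 = 207025-entry
feature correlation matrix. The `examples/` directory holds one short
script per capability.

A thin CLI mirrors the library:

```bash
canopyfeat synth --n 8 --out scenes --seed 42
canopyfeat extract --manifest scenes/manifest.csv --out features.csv
canopyfeat evaluate --pred pred.csv --obs obs.csv --task regression
```

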