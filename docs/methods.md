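# Methods

This note documents the models, conventions and design choices behind
plotpheno, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Geospatial conventions

Pixel indices are 0-based `(row, col)`; the world coordinate of a pixel is
its **center**. Rasterization includes a pixel iff its center lies strictly
inside the plot polygon (boundary ties excluded) — this makes membership
deterministic and exactly checkable against an exhaustive point-in-polygon
loop. Rasters are north-up with no rotation terms; the DEM must share the
orthomosaic's grid exactly, and misaligned grids are refused rather than
resampled, because any resampling choice would contaminate the canopy
metrics. Plot polygons may optionally be shrunk with a negative buffer
(default 0) to avoid edge pixels.

GeoTIFF I/O is a thin layer over `tifffile` handling the standard
georeferencing tags (ModelPixelScale, ModelTiepoint, a minimal
GeoKeyDirectory carrying an EPSG code, GDAL_NODATA). Shapefile polygon
layers are read and written directly (shape type 5 with dBase III string
attributes); dBase truncates attribute names to 10 characters, which is a
property of the format. Band roles (blue, green, red, rededge, nir) are
supplied explicitly by configuration; the default order matches the
five-band MicaSense RedEdge layout. 16-bit integer rasters are treated as
raw digital numbers (0–65535), float rasters as reflectance (0–1).

## Radiometric calibration

Empirical line calibration fits, per band, an ordinary least-squares line
of known panel reflectance against the mean digital number over each
panel's pixels (median available as an option; the mean is standard ELC
practice). At least two panels with distinct reflectances are required;
the per-band RMS fit residual is reported. Application clips to [0, 1]
and logs the clipped-pixel count per band; a scene already in reflectance
bypasses calibration with a notice, since pre-calibrated orthomosaics are
legitimate input. Calibration is per orthomosaic.

## Canopy segmentation

Vegetation is separated from soil on the green-minus-red (GMR) layer,
computed on reflectance (calibration precedes masking in the pipeline
order). The Otsu threshold uses a 256-bin equal-width histogram over the
observed range (GMR is continuous, not 8-bit; the bin count is
configurable), returns the interior bin edge maximizing between-class
variance, and breaks ties toward the lowest edge. Canopy is the high-GMR
class (plants reflect more green than red; soils the reverse). The
threshold is computed globally over the scene, before plot extraction; a
per-plot variant is available. Unimodal inputs (e.g. an all-soil
early-season scene) still produce a mask but log a warning when the Otsu
effectiveness ratio σ²_b/σ²_total at the chosen cut falls below 0.75 — a
split Gaussian tops out near 0.64 while clearly bimodal data approaches 1.

## Vegetation indices

All eight indices are normalized differences (a − b)/(a + b), so finite
values lie in [−1, 1] and swapping the bands negates the index. NDVI uses
the standard (NIR − R)/(NIR + R) ratio form. Zero-denominator pixels are
NaN and excluded from every downstream statistic — clamping them would
bias plot means. When a canopy mask is supplied, indices are computed on
canopy pixels only; unmasked computation is retained for map export.

## Canopy metrics

The ground reference per plot is the median DEM elevation over the plot's
soil pixels (identified by the canopy mask); when soil covers less than 5%
of the plot (closed canopy), the 5th percentile of all plot elevations is
used instead. Both the statistic and the fallback percentile are
configurable. Negative heights are floored at zero — heights are physical.

Per pixel: height = DEM − ground (canopy pixels only, NaN elsewhere),
cover = pixel area on canopy pixels, volume = cover × height. Per plot:
CHuav is the 95th percentile of canopy pixel heights with linear
interpolation between order statistics at index p·(n − 1) (the dominant
numeric convention, stated so tests are exact), computed over canopy-only
pixels (configurable); CCuav and CVuav are plain sums, so CVuav is
additive under plot splitting and equals the `canopy_volume_sum` feature
column by construction.

## Plot features

Seven statistics per layer: mean, **sample** variance (n − 1 denominator;
0 for a single pixel), median (mean of the central pair for even counts),
std, sum, min, max. Index and height statistics run over canopy pixels
only; cover and volume run over all plot pixels, because off-canopy zeros
are genuine area/volume contributions. 11 layers × 7 statistics = 77
feature columns per timing point, asserted on every table build. Plots
with zero canopy pixels get missing values (not zeros) for index/height
statistics, with a logged warning — zeros would fabricate spectral signal
— and are never dropped. Feature names are `{layer}_{statistic}`,
lowercase, in stable sorted order so CSVs are reproducible. Trait–feature
association uses Pearson r with the two-sided p-value from
t = r·√((n − 2)/(1 − r²)) on n − 2 degrees of freedom.

## Multi-temporal accumulation

Stages are EL (elongation), EBK (early bulking), LBK (late bulking), DMA
(dry-matter accumulation), in that order. A stage combination sums
(default; mean optional — correlations are invariant to the choice at
fixed combination size) each base feature over its member stages, adding
77 columns per combination. The shipped default set is all singletons,
all cumulative prefixes from EL, and the EL+LBK pair (8 combinations);
nine combinations yield the full 693-column predictor set, and the
nine-combination configuration used in tests adds EBK+LBK. The exact
combination set is configuration, documented as an interpretation: 693 =
77 × 9 fixes the count but not the membership.

## Yield prediction

Preprocessing per feature: shift to strict positivity if needed, Box-Cox
with maximum-likelihood λ, then min-max scaling to [−1, 1] using training
bounds. Box-Cox runs before scaling because the power transform requires
positive inputs; scaling to a range containing zero first would not be
executable. Constant training features are passed through with a warning
(the transform is undefined). Test rows reuse the stored training state
and may legitimately land outside [−1, 1]; they are not re-clipped.

PCA (centered, full SVD) reduces the predictor set; the default of 4
components follows an ~80%-of-variance rule and is configurable.
`pcr_regression` is principal component regression proper — OLS on the
scores — and with all components it reproduces the full OLS fit exactly
(the rotation is invertible). In the model-comparison report the "PCA"
variant feeds variance-ranked components to the regressors, while the
"PCR" variant re-ranks the same components by their training correlation
with yield (supervised selection in the PCR spirit) before feeding the
same regressors; this reading of the two-column comparison is an
interpretation and is labeled as such.

Four regressors: random forest, RBF-kernel support-vector regression,
k-nearest neighbours (ball-tree, uniform weights), and a single-hidden-
layer perceptron with ReLU activation trained by stochastic gradient
descent (hidden width 16 or 64 in the default grid; the architecture is an
interpretation, as only the training algorithm is pinned). Hyperparameters
are tuned by grid search minimizing 10-fold cross-validation RMSE; the
default grids are centered on operating points reported for this task (RF:
max_features 4, 100 trees; SVM: C = 2.1, RBF; kNN: K = 38) and extended
with standard neighbours — SVM γ ∈ {scale, 0.1, 0.3} and
C ∈ {0.7, 2.1, 6.3, 18.9}, RF min_samples_leaf ∈ {1, 5}, kNN
k ∈ {5, 12, 38}.

The train/test split follows the field design: whole replications train
(by default all but the last), one replication is held out — never random
rows, so genotype-plot structure cannot leak. Preprocessing and PCA are
fitted on training rows only and applied frozen to the test rows.
"Validation" metrics are 10-fold cross-validation means on the training
replications (labeled as such; a held-out validation split is the other
possible reading). "RMSE" is root mean square error; the reported RRMSE
percentages are consistent with the mean-based definition
RRMSE = 100 · RMSE / mean(observed). With fixed seeds the entire fit is
bit-reproducible.

## Synthetic trials

The generator emulates the structure the pipeline consumes: a gridded
field of rectangular plots (default 9 × 15 plots of 4 m × 4 m at 0.2 m
pixels), circular canopy blobs whose fraction and height grow through the
stages (EL 35%/0.5×, EBK 55%/0.8×, LBK and DMA 75%/1.0×), a gently
sloping ground plane, gray calibration panels of known reflectance in a
strip above the plots, and either float reflectance or 16-bit digital
numbers produced by inverting a known calibration line. Default spectra
put plant GMR at +0.15 and soil GMR at −0.02 with reflectance noise sd
0.01, a ~12σ class separation, so segmentation tests are meaningful rather
than fragile.

Per-plot variation comes from a vigor factor (sd 0.12, scaling plant
height and hence canopy volume) and an independent NDVI jitter (sd 0.03).
Root yield is yield = β₀ + β₁·NDVI + β₂·CV + ε on the true noise-free
features, with defaults β₀ = 5, β₁ = 40 (per unit NDVI), β₂ = 1 (per m³)
and ε sd 2.0 in yield units; the theoretical R² has the closed form
S/(S + σ²_ε) with S = β₁²σ²_NDVI + β₂²(CV_base·σ_vigor)², ≈ 0.67 at the
defaults — calibrated to the best-accuracy regime the models are expected
to reach. Replications are contiguous plot blocks, mimicking field
layouts; parameter-recovery runs use a 20 × 30 layout (600 plots, four
replications of 150, three training) whose trait table is generated
analytically from the latent truth without rendering rasters.

What the generator does **not** emulate: radiative-transfer effects,
shadows, genotype-specific canopy architecture, spatial autocorrelation
of soil or vigor, georeferencing error, and mixed pixels at canopy edges.
Passing tests therefore demonstrate the correctness of the computational
chain and its statistical behaviour under the stated model, not
performance on real imagery.

## Known limitations and honest numbers

On the 600-plot recovery task, SVR tracks the generator's theoretical R²
closely, while random-forest and k-nearest-neighbour test R² sit
systematically ~0.07–0.09 below it — the familiar attenuation of tree and
neighbour regressors on a continuous linear response — with an additional
±0.05-ish spread from the 150-sample test-split realization. This is a
property of the estimators, not a pipeline defect: OLS on the true
features reaches the realized ceiling. Problem sizes in the tests (compact
3 × 5-plot scenes for imaging, the 600-plot analytic table for modelling)
were chosen as the smallest trials that exercise every code path with
stable statistics.
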