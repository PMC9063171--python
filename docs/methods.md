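# Methods

This note documents the models, conventions, and numerical choices
behind `grainmetry`: a pipeline that estimates wheat mean grain weight
(MGW, mg) from top-view images of non-touching grains on a bright panel.

## Pipeline overview

1. **Resolution enhancement** (optional, recommended ×10): bicubic
   interpolation of the image before segmentation.
2. **Segmentation**: threshold the HSB brightness channel; grains are
   the dark side. Interior holes are filled; connected components are
   labelled; each grain's outer boundary is traced through pixel
   centres.
3. **Descriptors**: per-grain size/shape/intensity measurements
   (`Area`, `Perim.`, `Major`/`Minor`, `Feret`/`MinFeret`, `Circ.`,
   `Solidity`, `AR`, `Round`, `Skew`, `Kurt`).
4. **Indices**: a catalogue of 33 candidate weight predictors (the 12
   basic descriptors plus 21 ratios/products) plus the power-law control
   `Kim index = Area^1.32` (mm² basis).
5. **Models**: per-image arithmetic means are regressed against
   observed MGW (= weighed sample mass / grain count) by ordinary least
   squares; k-fold cross-validation reports held-out RMSE; transcribed
   published coefficients support direct prediction at three unit
   scales (original pixel, 10×-enhanced pixel, SI).

## Segmentation

* **Brightness channel.** HSB brightness = max(R, G, B) per pixel. On a
  lit white panel grains are darker than background, so foreground is
  the *darker* side of the threshold (an `--invert` flag exists for the
  opposite lighting).
* **Automatic threshold.** Iterative intermeans (IsoData): starting
  from the global mean intensity, the threshold is replaced by the
  midpoint of the two class means it induces until it converges. On a
  two-level histogram this converges to the midpoint of the two levels.
  Otsu and fixed thresholds are also available.
* **Hole filling** is applied before measurement: grains are solid
  objects and an interior specular highlight would corrupt area and
  solidity. The original acquisition's behaviour here is unknown; the
  choice is flagged and can be disabled (`holes_filled=False`).
* **Connectivity** defaults to 8 (diagonal pixels connect), the usual
  particle-analysis convention for convex-ish seeds. Labels follow the
  raster-scan order of each component's first pixel. No size or
  circularity filtering is applied; border-touching regions are kept by
  default (`exclude_edges` to drop them).
* **Boundary tracing.** Moore neighbourhood tracing, clockwise through
  pixel centres, starting at the top-left (raster-first) boundary
  pixel; a single-pixel region yields a one-point polygon.

## Descriptors

All geometry is on pixel centres; coordinates are 0-based (row, col);
angles are degrees counterclockwise from the +x (column) axis in
[0, 180).

* **Area** is the raw pixel count.
* **Perimeter.** Two estimators of the closed boundary chain exist:
  * the plain chain length (axis step 1, diagonal step √2), which is
    simple and exactly testable but overestimates smooth digitised
    contours by ≈5–6% *independently of resolution* (the classic
    Freeman-chain bias);
  * the Vossepoel–Smeulders corrected length
    `0.980·n_axial + 1.406·n_diagonal − 0.091·n_corners`, which is
    close to unbiased on smooth contours.
  The `Perim.` descriptor (and hence circularity and every index built
  on it) uses the corrected estimator. This matters: with the raw chain
  the *relative* error of circularity would grow under resolution
  enhancement (the bias persists while the half-pixel boundary inset
  shrinks), inverting the enhancement effect the pipeline is designed
  to exploit. `boundary_perimeter` still returns the plain chain by
  default for callers who want the textbook quantity.
* **Ellipse fit (`Major`, `Minor`, `Angle`).** Orientation and axis
  ratio come from the second central moments of the pixel coordinates;
  both axes are then rescaled by one common factor so that
  `π·(Major/2)·(Minor/2)` equals the pixel-count area *exactly* (to
  float precision, relative error ≲1e-13). `Minor` is the pipeline's
  measurer of grain width, `Major` of grain length.
* **Feret diameters.** Convex hull of the boundary pixel centres;
  `Feret` = maximum pairwise hull-vertex distance; `MinFeret` = minimum
  caliper width over hull-edge normals (rotating calipers — the minimum
  width of a convex polygon is always attained on an edge normal).
* **Circularity** `= 4π·Area/Perim.²`, capped at 1 (discrete perimeters
  of near-circular particles overshoot the ideal bound). **Solidity**
  is the boundary-polygon (shoelace) area over the convex-hull polygon
  area, capped at 1; the pixel-count area is *not* used here because
  counting whole pixels against a hull through pixel centres would
  systematically exceed 1. **Roundness** `= 4·Area/(π·Major²)`;
  **AR** `= Major/Minor`.
* **Intensity moments.** Skewness and *excess* kurtosis of the
  unweighted grayscale (channel mean) over the region's pixels;
  zero-variance regions report (0, 0) with a flag.
* **Units.** Descriptors are in pixels of the measured (possibly
  enhanced) image; when a mm-per-px scale is known, `*_mm` / `Area_mm2`
  companions are emitted. The scale is user-supplied configuration
  (default assumption 0.15 mm/px for synthetic scenes) — explicit beats
  inferred.

## Index catalogue and ranking

The catalogue evaluates 33 preliminary indices: the 12 basic
descriptors and 21 synthesized combinations (`Minor/Major`,
`MinF/Feret`, `Area/MinF`, `Area/Minor`, `MinF/Minor`, `Area/Perim.`,
`Minor/Perim.`, `MinF/Perim.`, `Area/Perim.^2`, `MinF x Area/Perim.`,
`Circ. x Solidity`, `Area x Circ.`, `MinF x Circ.`, `Minor/Solidity`,
`MinF/Solidity`, `Feret/Solidity`, `Area x Solidity`,
`Feret x MinF x Solidity`, `Perim. x Circ.`, and the five-factor
products `A1 = Area·Perim.·Circ.·Solidity·MinFeret` and
`A2 = Area·Perim.·Circ.·Solidity·Minor`). Two algebraic identities hold
for every grain by construction and are enforced in tests:

    Area  × Circ. = 4π·(Area/Perim.)²
    Perim. × Circ. = 4π·(Area/Perim.)

(`Area/Perim.^2` equals `Circ./4π`; it is kept verbatim for catalogue
coverage despite the redundancy.) The `Kim index = Area^1.32` is
computed on the mm² scale only — a power law is not unit-covariant — so
it appears whenever mm descriptors are available.

Ranking correlates per-*sample*-mean indices with MGW (Pearson R; the
sample, i.e. one image, is the analysis unit). An index is *selected*
when its |R| strictly exceeds both controls (`Area` and `Kim index`).

## Linear MGW models

`fit_linear` is simple OLS `MGW = slope·index + intercept` with R² and
population RMSE (divide by n). `kfold_cv` shuffles samples once with a
recorded seed, splits into k near-equal folds (n = 180, k = 10 gives
ten folds of 18), fits on k−1 folds and scores held-out RMSE, reporting
mean ± sd. Published slope/intercept pairs for the 12 retained indices
at three unit scales ship as a versioned CSV asset
(`grainmetry/data/published_models.csv`) and drive
`predict_published`.

## Synthetic scenes

The generator emulates the acquisition protocol end to end so that
every stage is testable without real images.

* **Grain dimensions.** (length, width) in mm from a bivariate normal —
  defaults: length 6.1 mm (CV 8.58%), width 2.9 mm (CV 12.36%),
  correlation 0.608 — induced via the Cholesky factor of the 2×2
  covariance, redrawing non-positive (or width ≥ length) pairs.
* **Weight law.** Per-grain weight (mg) = 26.22·width − 37.43 +
  N(0, 1.1). Weight is driven by *width*, not area, so ranking
  experiments have a known right answer; an area-driven law can be
  emulated by regressing on the emitted ground truth.
* **Silhouette.** A rotated superellipse with squareness exponent 2.5
  (wheat grains are rounder than rectangles, more angular than
  ellipses); exponent 2 gives exact ellipses for descriptor tests with
  analytic ground truth.
* **Rendering.** Flat grain intensity 60 on background 245 at an
  assumed 0.15 mm/px in a 960×720 frame. Edge pixels are *area-sampled*
  (4×4 subpixel coverage → mixed intensities), emulating a sensor pixel
  integrating light over its footprint. This matters: with hard binary
  edges, the level set of the bicubic upscale wiggles at the
  original-pixel scale and resolution enhancement makes shape
  descriptors *worse*; with area-sampled edges the enhanced threshold
  boundary tracks the true silhouette sub-pixel, and both `Minor` and
  `Circ.` errors shrink with enhancement (measured on exact-ellipse
  fixtures: 0.62%→0.17% and 6.4%→1.5% from ×1 to ×10). Optional
  Gaussian intensity noise on grain pixels; no texture or shadows.
  A pixel covered exactly 50% quantises to background, and the
  ground-truth mask uses the same strict rule, so the IsoData mask
  equals the ground-truth rasterization exactly on the packaged
  conditions.
* **Placement.** 450 grains in 960×720 at 0.15 mm/px is ≈46% effective
  coverage — close to the random-sequential-adsorption jamming limit —
  so placement uses shuffled jittered-grid candidates with a
  uniform-random fallback, placing the largest grains first, every
  candidate collision-checked against a gap-dilated occupancy raster
  (placed coverage fringes dilated by one pixel, probed with a
  half-pixel-inflated silhouette). This keeps the continuous
  silhouettes far enough apart that no pixel collects coverage from two
  grains and thresholding can never bridge neighbours; the labelled
  grains are at least 2 px apart. If a random sequence jams near the
  end, the canvas is cleared and repacked (up to 8 restarts, RNG stream
  advancing), which keeps generation deterministic under the seed and
  fast (~2 s/scene typical).
* **Datasets.** Samples cycle a 2×2 season × irrigation design with
  multiplicative mean shifts: season 2 shortens grains 2.48% and
  narrows them 1.57%; deficit irrigation shortens 1.38% and narrows
  5.13%. Scene seeds derive from a master seed. A fast sample-level
  simulator (`simulate_sample_table`) draws per-sample mean widths
  (group mean + width SD/√n_grains) and applies the weight law with
  sample-level noise (default sd 1.1 mg) for model-recovery
  experiments without rendering.

### What the generator does *not* emulate

Real images add texture, shadows, specular highlights, vignetting,
optical distortion, debris, and broken or touching grains; grain
silhouettes are not exact superellipses and real weight depends on
thickness and density, not width alone. Tests passing on these scenes
therefore validate the *measurement and modelling machinery* —
segmentation exactness, descriptor accuracy and convergence, estimator
recovery of a known generating law — not field-level predictive
performance, which can only be established on real archives.

## Numerical choices and degenerate inputs

* Bicubic kernel: Catmull-Rom a = −0.5 (Pillow's `BICUBIC`);
  intensities clipped, not wrapped, so edge overshoot cannot corrupt
  thresholding. Enhancement divides the mm/px scale by the factor.
* Intermeans iteration stops at a fixed point (≤256 iterations); a
  single-level histogram thresholds to an empty foreground.
* Ellipse fit requires ≥3 pixels; collinear pixel sets are reported as
  degenerate (minor axis 0). Single-pixel regions have Feret diameters
  0 (flagged); `measure_image` drops regions below 3 px with a warning.
* Circularity and solidity are capped at 1; zero perimeter or hull area
  raise errors naming the region.
* Ties in ranking are broken by index name for order stability;
  correlations of zero-variance columns report R = 0 with a flag.
* CV fold assignment is one seeded permutation, recorded in the output;
  RMSE is the population form.
* Scene generation, dataset seeds, and CV shuffles all flow from
  explicit integer seeds; identical seeds give bit-identical scenes.

## Problem sizes used in the packaged experiments

Synthetic experiments ship at the study's own scale where that is
cheap (450 grains/scene, 180 samples for sample-level model recovery,
ten-fold CV) and at reduced counts where full rendering is involved
(12 rendered samples for the index-ranking experiment; 12–24-grain
scenes for descriptor fixtures), chosen so the whole suite runs in
minutes on a laptop while keeping every statistical margin wide.

## Known limitations

* `Minor`/`Major` are *ellipse-equivalent* axes (area-preserving moment
  fit). For silhouettes fatter than an ellipse — e.g. the default
  superellipse exponent 2.5 — the ellipse-equivalent width exceeds the
  geometric width by a constant shape factor (~3.7% at exponent 2.5).
  Correlations and fitted models are unaffected (the factor is common
  to all grains), but closure checks against the generating weight law
  use exact-ellipse scenes where the conventions coincide.

* Absolute perimeter (and circularity) values depend on the boundary
  estimator; constant-factor differences against other tools cancel in
  fitted models but matter when comparing raw descriptor tables.
* The mm/px scale of the emulated acquisition is an assumption
  (0.15 mm/px); physical-unit results scale accordingly.
* `MinFeret` on coarse rasters is biased low by up to ~1 px (boundary
  through pixel centres); enhancement reduces the bias.
* The published-coefficient predictor is only as good as the transcribed
  table; it performs no unit checking beyond the declared unit system.
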