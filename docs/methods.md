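# Methods

This note records the models, conventions, and numerical choices behind
`fruitmorph`, and what the synthetic benchmarks do and do not demonstrate.

## Coordinate and raster conventions

Masks are boolean arrays indexed `[row, col]`, origin top-left, x = column,
y = row.  Polygon labels follow the YOLO Segmentation 1.0 dialect:
normalized (x, y) in [0, 1] relative to full image width/height, one polygon
per line, implicitly closed; both vertex orientations are accepted.
Rasterization fills pixel centers inside the polygon (even-odd rule).
Contours extracted from masks are sub-pixel marching-squares boundaries at
the 0.5 iso-level; refilling such a contour reproduces the mask exactly,
which makes mask → contour → mask a lossless round trip.

## Perimeter and circularity

The raw marching-squares boundary is a staircase whose arc length
overestimates a smooth object's perimeter by ~6%, which would bias
circularity (4π·area/perimeter²) down to ~0.90 for perfect discs.  The
perimeter is therefore measured on the boundary smoothed with a circular
moving average whose window is 2.5% of the contour's vertex count.  Because
the window scales with the contour, the estimate is scale-consistent, and
the residual bias shrinks as objects grow: digitized discs show circularity
rising monotonically with radius and settling at 1.000 ± 0.002 (values may
exceed 1 by up to the digitization tolerance 0.02).  The trade-off is that
very fine boundary texture below ~2.5% of the outline is treated as
digitization noise; for seed-scale objects at 4–6 px/mm this is below the
physical feature scale.

Hull area uses the convex hull polygon of the sub-pixel boundary rather
than a pixelated hull image; the latter would overestimate hull area by ~1%
on smooth convex shapes and push disc solidity below its ideal 1.

## Alignment

Orientation comes from the second-moment (inertia-equivalent ellipse) of
the mask, iterated up to three times because nearest-neighbour rotation can
perturb the moments; the residual is below 1°.  Near-isotropic shapes
(eccentricity < 0.1) are not rotated at all — a circle has no meaningful
major axis and resampling would only roughen it.  After rotation the shape
is flipped vertically so the tip (contour point farthest from the centroid)
lies in the lower half, then horizontally if the tip sits right of the
centroid.  All traits are measured in this canonical pose.

## Symmetry traits

The three symmetry indices are operationalized as mirror-overlap ratios
|M ∩ mirror(M)| / |M|: vertical and horizontal mirrors pass through the
centroid (stable under asymmetric outlines, unlike the bounding-box
center), and the shoulder index is the vertical overlap restricted to the
top 25%-of-length band (configurable).  These are this package's
definitions; other operationalizations of "symmetry" exist, and absolute
values should not be compared across software.

## Elliptic Fourier analysis

Coefficients follow the classical chain-summation closed form for a
piecewise-linear contour parameterized by cumulative chord length; DC terms
are the exact means of the piecewise-linear x(t), y(t).  Two
parameterizations are exposed: `chord` (default, sampling-density
independent) and `index` (uniform per vertex).  The distinction matters for
analytic fixtures: an ellipse traversed by arc length is *not* a pure first
harmonic (its x(s) is non-sinusoidal; the degenerate flat ellipse gives a
triangle wave), so exact single-harmonic recovery holds only under `index`
parameterization of angle-uniform samples.  First-harmonic normalization
(a₁ > 0, b₁ = c₁ = 0; rotation/starting-point/scale invariant) is available
but off by default, because shapes enter EFA already aligned and flipped by
the morphology stage.

## Shape PCA and registration

PCA is computed by SVD of the centered feature matrix; component signs are
fixed by making each component's largest-magnitude loading positive, and
the retention rule keeps all components explaining ≥1% of variance.  Mask
registration for pixel PCA is a single continuous affine warp (bounding-box
center to raster center, isotropic scale to fit 128×128 with a 2 px margin,
bilinear sampling, threshold 0.5); doing this in one sub-pixel transform
avoids the integer rounding jitter that separate crop/resize/pad steps
inject into the feature matrix.

A structural property of binarized masks is worth knowing: along any
one-parameter shape family, boundary pixels flip monotonically, so the
feature covariance has the Brownian-bridge form min(F_s,F_t) − F_s·F_t and
the leading eigenvalue fraction saturates near 6/π² ≈ 0.61 regardless of
how "one-dimensional" the family is.  PB-PC1 therefore dominates and orders
such a family, but cannot capture ≥90% of pixel variance; the EFA basis,
being smooth in the parameter, does (≥0.9 measured on elongation families).
k-means uses best-of-10 restarts under a shared seed so the
within-group-sum-of-squares curve is reproducible and non-increasing.

## Thickness model

Degree-1 (`1, A, W`) or degree-2 (`1, A, W, A², W², A·W`) least-squares
surfaces on raw (unstandardized) predictors, so coefficients stay in
natural units.  Validation repeats random 80/20 splits 100 times (the
protocol's default) and reports per-repetition test R²/RMSE, their medians,
and the best repetition; a full-data refit is reported separately by
`fit`.  Shell thickness is out of scope: shells vary too much in density
for a weight-based surrogate.

## Heritability

The model is Y_ijk = μ + G_i + Y_j + ε_ijk with genotype random and year
fixed.  Estimation is REML profiled over λ = σ²G/σ²e: the marginal
covariance is block diagonal with blocks I + λJ per genotype, so the
criterion is a closed-form 1-D function of λ, minimized by a coarse
log-grid (e^-14..e^8) plus bounded refinement (xatol 1e-12).  On balanced
designs this coincides with the expected-mean-squares ANOVA estimator to
~1e-7, and with an off-the-shelf mixed-model REML fit to that package's own
convergence tolerance.  H² = σ²G/(σ²G+σ²e) is per observation — the
residual variance is not divided by the replicate count — matching the
definition as printed; a per-genotype-mean variant can be derived from the
reported components if needed.  Negative genetic-variance solutions are
truncated at 0 and flagged as boundary fits.

## Camera and color calibration

Planar-target calibration: per-view DLT homographies (Hartley-normalized)
give closed-form zero-skew intrinsics and extrinsics, refined jointly with
radial (k1, k2, k3) and tangential (p1, p2) distortion by
Levenberg–Marquardt on total reprojection error.  Undistortion resamples by
inverse mapping; point undistortion inverts the distortion by fixed-point
iteration (20 iterations, sub-0.5 px over typical fields).  Color
correction is one affine map in RGB fitted from ≥4 chart patch pairs by
least squares; geometric correction is applied before photometric.  Chart
and corner *detection* are out of scope — patch means and corner grids are
inputs.

## Synthetic generator

The outline family is parameterized by t ∈ [0, 1] from shoulder to tip:
y(t) = −(L/2)cos(πt) and total width W·f(t)/max f with
f(t) = sin(πt)^p·(1 + s·t); lateral asymmetry ℓ splits the width into
(1±ℓ)/2 shares.  p = 1 with zero asymmetries is exactly an ellipse, so
areas, widths-at-depths, and symmetry have closed-form or quadrature truth.
When the skew makes the top pole the farthest-from-centroid point, the
canonical pose is flipped and the stored widths-at-depth truths follow.
Default sampling (lengths 20–32 mm, width 45–70% of length, p 0.6–1.0,
s ±0.25, ℓ ±0.06, rendered at 6 px/mm) emulates the spread of kernel and
shell populations and the higher-resolution imaging season; scenes place
shapes in a jittered grid on a dark background (level 15) with tan-brown
per-seed color and mild sensor noise, optionally pushed into 1–20% overlap
to exercise watershed separation.  Thickness triples default to areas
120–320 mm², weights ≈ 0.0048·area ± 15%, and residual SD 0.47 mm — the
residual scale reported for real kernels.  Phenotype tables follow the
mixed model exactly, with observations split evenly across years.  One
global seed fans out to per-component generators via `SeedSequence` keyed
by a CRC of the component name, so any subset of the suite reproduces in
isolation.

What the generator does *not* emulate: wrinkled kernel texture, specular
highlights, shadows, debris, chart/corner detection failures, and
non-grid layouts.  Passing tests demonstrate correctness of the
measurement and statistical machinery on realistic geometry, not detector
robustness on real imagery.

## Problem sizes used in the automated checks

The shipped test suite and acceptance script use: 100 random masks for
slice/reconstruct identity; 50 (tests) or 20 (script) simulated 30-seed
scenes for count recovery; 200 (tests) or 100 (script) generated shapes
for the morphology oracle; 20 random 50×20 matrices for the PCA oracle;
227-row thickness datasets (the fitted sample size) with 100-split
validation; and 200 genotypes × 10 observations × 2 years with 50 (tests)
or 30 (script) replicates per true H² for heritability recovery.  These
sizes keep the full verification run to a few minutes on one core while
holding the estimator standard errors well inside the asserted tolerances.

## Known limitations

* Classical Otsu thresholding stands in for a learned segmenter; it
  assumes bright objects on a dark background and will not handle complex
  scenes — any external detector's masks or polygons can be substituted at
  the same interface.
* Watershed seeding needs a sensible minimum peak distance (~half the
  expected minor axis); badly wrong values over- or under-split.
* The error-accounting QC flags (undersize, border, count mismatch)
  approximate "incorrectly reconstructed"; visual review remains the
  authority on real data.
* Trait absolute values depend on the stated conventions (perimeter
  smoothing, symmetry definitions, registration raster); comparisons across
  software should be made on rank or correlation scales.
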