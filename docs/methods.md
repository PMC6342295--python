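# Methods

## Scope and data model

`canopy3d` operates on already-rasterized photogrammetry products: a
digital surface model (DSM) and, optionally, NIR/RED reflectance bands,
all as single-band GeoTIFFs in a projected, metre-unit CRS. Geographic
(degree) rasters are rejected because every stage multiplies pixel
sizes into areas (m²) and volumes (m³). The grid convention is
pixel-centre sampling on a north-up affine (row 0 northernmost); all
lengths are metres internally. Point-cloud processing, mosaicking,
orthorectification and the photogrammetric reconstruction itself are
out of scope — the pipeline starts where the GIS raster work starts.

## Terrain model

The DTM is rebuilt from the DSM by sampling ground elevations in the
open inter-row/intra-row zones and triangulating them:

- **Canopy exclusion.** Either a caller-supplied mask or a provisional
  rule: DSM minus a coarse per-block median (block = 5 m, at least the
  tree spacing, so each block keeps a ground majority) exceeding 0.5 m,
  dilated by 3 pixels.
- **Sampling.** One sample per tile of a regular grid (default step
  2.5 m = half the tree spacing); the sample is the 10th-percentile
  elevation among non-excluded pixels in the tile, placed at the pixel
  realizing it. The low percentile is robust to stray low vegetation;
  on sloping ground it biases each sample toward the downhill edge of
  its tile by at most gradient × step, which is millimetres at
  orchard-scale gradients.
- **Interpolation.** Delaunay triangulation with piecewise-linear
  interpolation inside the convex hull (exact for planar terrain;
  error bounded by the terrain's second-order variation across one
  sampling step, tested on quadratic terrain), nearest-point outside.

nDSM = DSM − DTM with negative cells clamped to zero: sub-terrain
heights are interpolation noise and would corrupt volume sums. When a
surveyed DTM exists it can be passed directly, skipping derivation.

## Crown delineation

Local thresholds are computed on the nDSM, not the raw DSM, so the
terrain trend does not leak into the local statistics. Three methods:

- Niblack: foreground iff value > m_w + k·s_w (default k = −0.2);
- Sauvola: iff value > m_w·(1 + k·(s_w/r − 1)) (default k = 0.5,
  r = half the nDSM value range) — the default method, more stable on
  large flat backgrounds;
- fixed: iff value > height threshold (default 0.5 m).

Window statistics use the window **clipped at the raster border**
(unbiased edge statistics), implemented with integral images so cost
is independent of window size; the default window is ~1.5 × the
expected crown diameter in pixels. Equality with the threshold is
background, which makes the zero-variance (constant) case well
defined. Components are 8-connected; those below 0.5 m² are dropped as
noise specks; labels are assigned in raster-scan order of each
component's top-left pixel. No watershed splitting is attempted:
touching or overlapping crowns are out of scope (hedgerows, very dense
plantings).

## Per-tree traits

- **Height** = max DSM over the segment − mean DTM over a 2 m-wide
  annulus around it, canopy pixels excluded. On planar terrain the
  symmetric annulus averages to the terrain at the crown centre. The
  DTM (not the DSM) supplies the surrounding-terrain reference.
- **Diameter** = 2√(area/π) of the footprint — the equivalent-circle
  diameter; for an elliptical footprint this is the geometric mean of
  the two axis diameters.
- **Volumes**: total = Σ area·height over the footprint; below-canopy
  prism = footprint area × clearance d (fixed orchard mean 0.7 m, or
  per-tree measured values); net = total − below, clamped at 0 with a
  warning (a fixed d can exceed a small tree's mean height).
- **Field formulas** kept for comparison: ellipsoid volume
  (4π/3)(D1/2)(D2/2)((Ht−Hb)/2) and trunk cross-sectional area
  C²/(4π).
- **NDVI** per pixel with zero-denominator cells as nodata; per-tree
  vigour is the mean over the footprint. SPAD converts to chlorophyll
  via Cab = 0.8271·SPAD − 12.8; SPAD below ≈15.5 is outside the
  calibration domain and returns a negative Cab with a warning rather
  than silently clipping.

## Water status

The water stress integral follows Myers' step-function formulation:
interval means of consecutive stem-water-potential measurements,
deviation from the seasonal maximum c within the analysis window
(default DOY 182–273), weighted by interval length, absolute value.
WSI is reported positive (MPa·d) and daily WSI = −WSI/n_days negative
(MPa); both conventions appear in field reports, so they are fixed
explicitly. c is per series; a caller-supplied reference supports
per-treatment alternatives. Irrigation arithmetic: requirement =
effective ET × Kc × Kr (defaults 0.55, 0.46) and litres per tree =
per-hectare volume ÷ tree density from the planting grid.

## Validation statistics

- Origin-forced fit: slope Σxy/Σx², with the uncentered
  R² = 1 − Σ(y−ŷ)²/Σy² (the centered form can be negative for
  through-origin fits and is not what such reports use); recorded in
  the result metadata.
- Ordinary least squares with centered R²; residual RMSE uses divisor
  n, not n − p, matching how validation residuals are reported.
- Bilinear (two-segment continuous) regression by profiled grid search
  over candidate breakpoints (default 200 points spanning the x-range):
  deterministic, no starting values. Candidates need ≥2 points on each
  side, otherwise the hinge column is collinear; a flat SSE profile
  (single-line data) is flagged non-identifiable.
- Multiple regression with two predictors (daily WSI, NDVI) plus
  intercept; rank-deficient designs are rejected. Coefficients are
  always estimated from data, never assumed.
- No multiple-testing correction is applied: per-date fits are
  reported raw, deliberately mirroring standard field-validation
  practice.

## Synthetic scenes: what they emulate, and what not

The generator renders a grid-planted orchard (defaults: 3 × 5 trees at
5 × 5 m, 2 cm GSD) on a plane-plus-smooth-undulation terrain
(gradient (0.01, 0.005) m/m, 0.15 m amplitude at ~15 m wavelength).
Crowns are upper half-ellipsoids: semi-axes a = D1/2, b = D2/2,
c = (Ht−Hb)/2, equator at terrain + Hb + c, apex at terrain + Ht.
Defaults draw D1, D2 ∈ [2.2, 3.6] m, Ht ∈ [2.1, 3.9] m,
Hb ~ N(0.7, 0.05) m, giving crown volumes of roughly 3–22 m³ —
a mature olive planting. Two analytic truths accompany each tree: the
ellipsoid volume and the surface integral ∫(z_top − Hb) dA =
(5/3)πabc, verified independently in the suite by brute-force
quadrature before anything downstream relies on it. The optional vase
core is a conical depression (radius and depth fraction f of the
crown), removing (2/3)πabc·f³ — enough to reproduce the qualitative
fact that surface integration reads *below* the ellipsoid formula on
vase-trained trees.

Reflectance is minimal by design: canopy NDVI rises linearly with leaf
area index from 0.30 to 0.70 over the configured LAI range, soil sits
at 0.10, NIR + RED is fixed at 0.6 and both bands are back-solved from
NDVI plus Gaussian noise (sd 0.01). Stem-water-potential fixtures hold
irrigated trees in [−2.2, −1.4] MPa and march rainfed trees from −1.5
to −4.5 MPa with a mid-season rain recovery.

What the generator does **not** model — and therefore what green tests
do *not* demonstrate about real data: photogrammetric reconstruction
error (doming, smoothed crown edges, holes), georeferencing error,
under-crown occlusion effects beyond the simple core depression,
radiative transfer (shadows, soil brightness, view geometry), crown
asymmetry and touching crowns. Field validation slopes of ~0.9 and R²
of 0.7–0.9 reflect those error sources; on clean synthetic scenes the
pipeline recovers volumes with slope ≈ 1.00 and R² > 0.99, which is a
check of correctness, not a field-accuracy claim.

One RNG master seed derives independent sub-streams per raster, so a
scene is bit-identical under the same seed and config.

## Numerical choices and degenerate inputs

- Threshold ties → background; nodata → background.
- Integral-image moments in float64; variance clamped at 0 before the
  square root.
- Centroid matching is greedy nearest-first with deterministic
  tie-breaks (segment label, then tree order), default gate 2.5 m
  (half the spacing).
- All-nodata rasters write with a warning; empty segments integrate to
  zero volume; an empty terrain annulus, an all-excluded ground mask,
  collinear ground points, degenerate ellipsoid heights (Ht ≤ Hb) and
  non-increasing day grids raise errors rather than guessing.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
default 15-tree scene at 2 cm GSD (1250 × 750 cells) and the
single-tree convergence study at 4/2/1 cm; these sizes exercise every
code path at the study's native resolution while keeping a full run in
the seconds range on a single CPU.

## Known limitations

- One crown per connected component: no splitting of merged crowns.
- The DTM derivation assumes visible ground between rows; closed
  canopies would starve the ground sampler (it errors below 3 points).
- The below-canopy prism uses a single clearance per tree; real crown
  bases undulate.
- GeoTIFF support covers the single-band, metre-unit case the pipeline
  needs (pixel scale, tie point, nodata); it is not a general GeoTIFF
  library, and CRS reprojection is out of scope.
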