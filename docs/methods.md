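# Methods

This note records the models, conventions and numerical choices behind
`corticalmap`, in the order the pipeline applies them, together with
what the synthetic validation does and does not establish.

## Geometry

**Axis.** The shaft's long axis is the first principal direction of the
periosteal vertex cloud (SVD of centered vertices).  We deliberately do
not use the LM1–LM2 chord as the axis: the cutting planes are meant to
be orthogonal to the long axis of the shaft, and a principal direction
is robust to landmark placement noise; the landmarks only orient the
sign (LM1 must project proximal of LM2, so swapping the landmarks flips
the orientation and the asymmetric crop margins follow the landmarks,
not the coordinate frame).  A cloud whose first two singular values are
within a factor 1.5 has no meaningful axis and is rejected.

**Crop.** The two margins (defaults 0.10 proximal, 0.05 distal) are
fractions of the *step-1 axial span* — the LM1-to-LM2 distance along the
axis — not of total bone length.  The spec of the crop is "remove a
margin of the landmark-bounded cylinder", and span fractions are the
only reading that keeps the crop independent of how much epiphysis is
present in the scan.  Cropping slices the mesh with exact edge
splitting (no vertex snapping); the cut leaves open rings.

**Volume.** Shaft volume closes each boundary ring with a planar
triangle fan about the ring centroid and applies the divergence theorem
to the resulting closed surface.  The endosteum is ignored: the medulla
is included by definition.  On an analytic cylinder the relative error
is set by the angular chord (sagitta ≈ R·(2π/n)²/8); 128 angular
segments give ≲0.05%.

**Thickness.** Cortical thickness at a periosteal vertex is the exact
minimal distance to the endosteal *surface* (point-to-triangle), not to
the nearest endosteal vertex.  The implementation takes k-nearest
triangle centroids as candidates, then exhaustively tests every triangle
whose centroid lies within the candidate bound plus the mesh's largest
triangle circumradius, so the result equals the brute-force minimum to
floating-point precision (verified to ≤1e-9 in tests).

**Unrolling.** Each cropped periosteal vertex maps to
`x = (s − s_min)/(s_max − s_min)` (axial fraction of the kept span) and
`y = azimuth/2π` about the axis, measured from the meridian through
LM1's radial projection.  Right bones use the right-handed azimuth about
the proximal→distal direction; left bones are mirrored (`y → 1 − y`), so
a mirrored mesh with flipped laterality yields the identical cloud.
Only the normalized coordinates matter downstream, so the projection
cylinder's diameter is irrelevant to the statistics.  A specimen whose
LM1 lies on the axis has no defined cut meridian and is rejected.

## Standardization and smoothing

Thickness is min-max scaled to [0,1] per specimen before smoothing;
a constant field (degenerate) maps to 0.5 everywhere with a warning.
Note the consequence: the maps carry *relative* topography only, so
absolute wall-thickness differences between specimens are invisible to
the map statistics (they remain visible to the volume analyses).

The smoother is a low-rank thin-plate-spline regression: a ~300-knot
grid carries the radial basis `r² log r`; the affine null space
(1, x, y) is unpenalized; the bending-energy penalty is the kernel
matrix projected onto the polynomial-orthogonal complement (so the
penalized quadratic form is positive semidefinite).  The smoothing
parameter is selected from a 25-point logarithmic grid (1e-8…1e2,
penalty trace-normalized and scaled per observation) by GCV,
`n·RSS/(n − edof)²`.  Design choices that matter:

- **Circularity.** The circumferential coordinate is periodic: points
  within 0.15 of the seam are duplicated one period away before fitting,
  and predictions wrap `y mod 1`.  A thickening straddling `y = 0/1` is
  reconstructed as one contiguous feature, not two half-bumps.
- **Weighted GCV on distinct observations.**  Exactly repeated
  `(x, y, z)` observations are collapsed into frequency weights, and GCV
  counts distinct observations with RSS normalized by the mean weight.
  This makes pooled fits of duplicated clouds *exactly* equal to the
  single-cloud fit (plain GCV shifts the selected λ under duplication
  because `edof/n` changes), and reduces to standard GCV when all
  weights are one.
- **Grid conventions.**  Nodes sit at cell centers `((j−½)/M, (i−½)/K)`
  with M = 100 columns (axial) and K = 200 rows (circumferential); the
  long form lists K·M = 20,000 rows in row-major order (y outer, x
  inner).  Smoother overshoot outside [0,1] on standardized maps is
  clipped with a logged count.
- **GCV scale.**  The GCV score is reported as a fit diagnostic; its
  absolute scale depends on the augmentation and weighting described
  above, so only comparisons within this package are meaningful.

With 5,000 noiseless samples of a smooth field the grid reproduces the
field to ≤0.01 max error; through the full mesh pipeline (where the
min-distance metric and mesh discretization add error) reconstruction is
within 5% of the standardized range away from degenerate loci.

## Statistics

**Permutation MANOVA/MANCOVA.**  Sequential (Type I) sums of squares
from orthonormal incremental bases on the high-dimensional response;
pseudo-F is Goodall-style (trace SS ratios).  Because the maps already
share a common frame, no superimposition is performed — this is the
distance-based linear-model ANOVA that shape analysis applies to
aligned configurations, and the one-way case reproduces PERMANOVA on
Euclidean distances exactly (cross-checked against scikit-bio in the
tests).  p-values use residual randomization (RRPP): for each term,
residuals of the reduced model containing all preceding terms are
permuted, and the F statistic is recomputed in full.  All permutation
p-values use the `(b+1)/(B+1)` convention (B = 1000 by default), so the
minimum attainable p is `1/(B+1)` and p = 0 never occurs.  Confounded
terms are dropped with a warning.

**PCA + CVA.**  PCA retains the smallest number of components reaching
95% cumulative variance.  CVA solves the generalized eigenproblem of
between- vs pooled-within covariance on those scores (ridge jitter with
a warning if the within matrix is singular), with axes scaled to unit
within-group variance.  "Theoretical extreme maps" back-project the
observed minimum and maximum canonical score on each axis through the
pseudo-inverse of the axis matrix and the PCA loadings into a K×M grid.

**Two-block PLS.**  SVD of the cross-covariance between the centered map
block and the unit-variance-standardized trait block (traits mix kg,
months and cm³, so standardization is required for the cross-covariance
to be meaningful).  The first-dimension correlation is tested by
permuting trait rows.  Singular values are non-increasing by
construction; the per-dimension score correlations are reported and lie
in [0,1] but are not guaranteed monotone.

**Scalar traits.**  Factorial ANOVA via OLS (interactions dropped
automatically if the design is saturated), Pearson tests, per-group
simple regressions with 95% CIs, and pairwise t-tests with Bonferroni
correction (`p·k` capped at 1; groups of size 1 excluded with a
warning).  ACSA = (mass/1.06)/fascicle length, in cm².

## The synthetic generator

A specimen is a tube of length 120 mm, outer radius 10 mm (optionally
waisted), wall `base_wall + Σ` periodic Gaussian bumps in fractional
(axial, angular) coordinates.  The endosteum is the periosteum offset
inward along the local radial direction, so the radial wall field is the
exact analytic truth; bumps wrap across the angular seam so entheses
near the cut line are not split artifacts.  CT-like volumes rasterize
the solid between the surfaces with bone-thick end caps (so the
medullary cavity is enclosed, as the distal fork encloses a real one)
and exactly two intensities.  Cohorts plant effects at the
bump-amplitude level — group mean amplitudes, a trait loading on the
standardized body mass, and Gaussian amplitude noise — which keeps
per-specimen analytic truth available for oracles; metadata and muscle
tables are drawn from stated Gaussians, fully determined by the seed.

Reference study conditions: calibration cohorts use two groups of 8 on a
25×50 grid with an anchor bump (1 mm) pinning the standardization range
and an effect site carrying the planted difference; the map-level
("analytic") route evaluates the exact fields on the grid rather than
running 200 × 16 mesh pipelines, because the quantity under test there
is the behaviour of the statistics, not mesh measurement error (which
the mesh-route tests cover separately).  The allometric recovery study
uses n = 23 per cohort with slope 0.20 and residual noise set from the
target R² = 0.89 via `σ = slope·sd(mass)·√(1/R² − 1)`.

**What passing these tests does not show.**  Real bones are not tubes:
curved shafts, non-convex sections, open segmentation defects, nutrient
foramina, and trabecular remnants all perturb the axis fit, the
unrolling, and the thickness metric in ways the phantoms do not probe.
The generator also plants effects as smooth Gaussian fields; real
entheseal signals are rougher and the smoother's GCV behaviour on them
is only bounded, not verified.  Group labels, not biology, drive the
planted differences — calibration results say the tests are valid and
powered under the stated conditions, nothing more.

## Known limitations

- The axis is straight; strongly curved diaphyses would need a
  centroid-line parameterization, which is out of scope.
- Multiple internal cavities in a segmented volume are resolved by
  taking the largest, with a log message; no claim is made that this
  matches any particular commercial segmentation tool.
- Min-max standardization discards absolute thickness; covariation
  carried by absolute scale is detectable only through bone volume.
- The GCV score's absolute value is implementation-specific (see above);
  consensus GCVs should be compared only within this package.
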