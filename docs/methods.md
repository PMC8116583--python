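# Methods

## The indicator model

An imaging indicator of the optic disc (IOD) for a choroidal-thickness
target y (mChT or pChT, μm) is a linear score

    IOD = (b0 + Σ_j b_j · z_j) / 10,        z_j = (x_j − μ_j) / σ_j,

where x_j are selected imaging features, μ_j/σ_j are training-set means and
standard deviations, and b are unpenalized OLS coefficients of y on the
standardized features. Dividing by 10 expresses the indicator in 10-μm
units. Because the intercept of an OLS fit equals the training mean of y,
the cohort mean of the indicator times ten reproduces the cohort mean ChT —
a useful sanity identity that the tests assert.

Feature selection is two-staged:

1. **Ordering.** A LASSO regularization path (decreasing λ, 200 grid
   points, features standardized with training statistics only) is fitted
   to the training set; features are ranked by the λ at which they first
   enter with a nonzero coefficient. Ties are broken by larger absolute
   correlation with y, then lexicographically. Zero-variance columns are
   excluded with a warning. The L1 path is used only for ordering — it
   handles the heavy collinearity of a radiomic pool — never for the final
   coefficients.
2. **Stopping.** For each k, the first k features are refit by OLS on the
   training set, and adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1) is
   evaluated on both sets. The chosen k\* is the largest k whose prefix of
   test-set adjusted R² values is strictly increasing, i.e. the curve's
   first local maximum: the model grows while out-of-sample fit still
   improves and stops at the first sign of redundancy/overfitting. This is
   a deliberately greedy, deterministic rule; it does not look past the
   first dip.

Standardization parameters always come from the training split; the test
set is used only to evaluate the per-k adjusted R² (the quantity the
stopping rule is defined on) and for final reporting.

## Geometry

* **Magnification.** Pixels convert to mm via t = p · q with
  q = 0.01306 · (AL − 1.82) (Bennett's axial-length-only adjustment of
  Littmann's telecentric formula). The camera constant p is an instrument
  property; the default maps a mean eye (AL 25.51 mm) to 0.0075 mm/px at
  1024² resolution. Accepted AL range (15, 40) mm.
* **Disc shape.** LD/SD are the contour extents along the principal axes of
  the contour polygon's second moments (Green's-theorem moments — stable on
  rasterized, slightly noisy contours; an exhaustive chord search would be
  O(N²) and noise-sensitive). Ovality = SD/LD. Torsion is the signed angle
  between the long axis and the perpendicular to the disc-center→fovea
  line: positive when the superior (image-up) end of the long axis leans
  toward the nasal side, negative toward the temporal side. The convention
  is anatomical, so mirroring an entire case (fellow eye) preserves the
  sign, while flipping the tilt relative to the disc–fovea axis reverses
  it. Discs with ovality ≥ 0.995 have numerically degenerate axes and
  report torsion 0.
* **PPA.** Area is the polygon area of the PPA region minus its overlap
  with the disc, perimeter the length of the annotated PPA contour, and
  width the chord of the PPA region along the disc-center→fovea ray (for a
  crescent between radii r₁ and r₂ this reproduces the radial thickness
  r₂ − r₁). Disc–fovea distance is measured from the disc centroid; the
  margin-to-fovea alternative would differ by about one disc radius and is
  not used.
* **ROIs.** ETDRS circles (3/6-mm diameters; plus the 1-mm central circle
  in macular mode) are centered on the disc centroid. Quadrants are 90°
  sectors centered on the temporal axis (disc→fovea), its opposite (nasal)
  and the two perpendiculars, with superior on the image-up side — all
  directions derive from the annotation, so nothing downstream hard-codes
  eye laterality. The inner ring excludes the disc but keeps PPA pixels:
  the atrophy signal adjacent to the disc is precisely what the temporal
  features should see. The eight ring-quadrant regions (2 rings × 4
  quadrants) are pairwise disjoint; the extraction ROI "I" is the full
  inner ring, of which "IT" is the temporal quadrant. Vessel pixels are
  removed from every mask; membership is a pixel-center test.

## Radiomic operators

Standard formulations: population (biased) moments for first-order
statistics; symmetric distance-1 co-occurrence matrices averaged over the
four 2D directions (averaging, not merging); run-length matrices per
direction with runs broken by the mask; size zones by 8-connectivity;
NGTDM/GLDM on Chebyshev-1 neighborhoods ignoring out-of-mask neighbors
(GLDM dependence = 1 + number of same-level neighbors, α = 0). Channels are
CIELAB under D65 from sRGB, affinely mapped to a nominal [0, 255] scale
(L·2.55, A+128, B+128) — a fixed affine, never per-image min–max, so range
and higher-moment features remain comparable across cases. Discretization
is fixed-bin-width (default 25) anchored at the masked minimum, level i
covering [min+(i−1)w, min+iw). The shape perimeter uses the 4-direction
Crofton estimate, which is unbiased on smooth boundaries where the raw
marching-squares polyline overestimates by the staircase factor (a
rasterized circle then satisfies the isoperimetric identity to <1%).

Degenerate-region conventions, fixed and tested: skewness 0, kurtosis 0 on
constant regions; GLCM correlation 1 and MCC 1; IMC1 0; NGTDM coarseness
capped at 10⁶. An empty ROI flags the case (features NaN) rather than
dropping it silently; flagged cases are excluded from modeling and listed
in the run summary.

Every texture feature is verified against an independent brute-force
implementation (plain per-pixel/per-pair loops, no shared code) on ≥100
random masked patches to 1e-10, and GLCM matrix construction additionally
against scikit-image's `graycomatrix`.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
photorealism. Per subject: AL ~ N(25.51, 1.34²) truncated at ±3.2 sd;
a latent standard-normal "atrophy severity" couples the eye's appearance to
its choroid. ChT decomposes as

    ChT = mean − slope·(AL − 25.51) + sqrt(f)·sd·Z + e,    Z = −severity,

with f = `signal_fraction` (default 0.5) the fraction of ChT variance
carried by the image signal, slope 23 μm/mm for mChT (≈25% of variance via
AL, matching a cohort-typical AL–ChT correlation near −0.5; scaled by
sd-ratio for pChT), and independent noise e sized to hit the target total
variance. Ovality (truncated normal, anti-correlated with AL and severity),
torsion N(4.98, 19.78²), and PPA area (lognormal matched to mean 0.68 / sd
0.63 mm² — a normal would go negative — with its log-scale driver
correlated with AL and severity) complete the morphology. Age is uniform
16–40, sex Bernoulli(0.5); blood pressure, IOP (truncated ≤21 mm Hg), ACD,
refraction (SER tracking AL), BCVA, retinal and RNFL thicknesses get
plausible cohort-style marginals.

Rendering (right-eye layout, fovea temporal along +x): a flat
fundus-colored Lab background with mottled texture, an elliptical disc with
the planted semi-axes and torsion, a temporal crescent solved by bisection
to the planted PPA area, 4–8 dark vessel arcs with an exact vessel mask,
and — in the temporal sector — an additive texture field u^γ (u uniform)
whose per-channel amplitude and shape are the planted intensity
parameters: amplitudes (hence ranges) increase and γ (hence skewness)
shifts with severity, so a thinner choroid looks brighter, more desaturated
and more variable temporally. Planted "range" is the field amplitude and
planted "skewness" the closed-form skewness of u^γ; the 8-bit sRGB
round-trip, background noise and PPA overlay perturb the extracted values
by a roughly case-constant offset, which preserves the correlation
structure the pipeline consumes (the geometric plants — ovality, torsion,
PPA area — are recovered exactly). The camera field of view and pixel
pitch are not cohort-constrained anywhere; defaults (1024 px at a nominal
0.0075 mm/px, widened 15% so the 6-mm circle and fovea fit at every sampled
AL; disc–fovea distance 4.4–4.7 mm, clamped to the field when a short eye
images small) are stand-ins chosen for geometric consistency.

What the synthetic data does **not** emulate: real choroidal/vascular
texture statistics, illumination gradients and media opacities, annotation
error (contours are the exact rendering inputs), and any nonlinearity in
the appearance–ChT relationship. Passing tests therefore demonstrate that
the machinery recovers a known linear signal under realistic marginals and
collinearity — not that the shipped feature sets transfer to clinical
photographs.

A tabular mode (`synthetic_feature_table`) emits the feature table the
extraction stage would produce — planted geometric and intensity features
plus measurement noise and nuisance columns — directly from ground truth.
Large many-seed experiments (the 20-cohort recovery check, the modal-k\*
simulation at n = 600 with six planted features under noise giving
R² ≈ 0.75) run in this mode; the image path is exercised end to end at
smaller sizes (tests: 14–48 cases at 256 px), problem sizes chosen to keep
the default suite quick while leaving every stage covered at full fidelity.

## Statistics

Spearman with average ranks, two-sided p; partial correlation by OLS
residualization on covariates (t reference with n−2−k df; a variable fully
explained by its covariates reports r = 0, p = 1 rather than numerical
noise); Student's t (equal variances) and χ² without continuity correction
for cohort comparisons, with a Kolmogorov–Smirnov normality flag per
variable; standardized β = B·sd(x)/sd(y). Two-sided p-values throughout and
no multiple-testing correction — matching the reporting style the pipeline
mirrors; interpret large correlation tables accordingly.

## Known limitations

* The stopping rule is greedy; a later second rise of test adjusted R²
  (possible at small n) is never reached.
* Crofton perimeters slightly underestimate polygonal shapes with long
  axis-aligned edges (~6% on a rectangle); all ophthalmic ROIs here are
  smooth, where the estimator is accurate.
* GLDM dependence counts include the center pixel (k ≥ 1); other
  conventions shift the matrix by one column.
* The generator's appearance–severity coupling is monotone and linear in
  the planted parameters; it cannot probe robustness to non-monotone
  appearance changes.
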