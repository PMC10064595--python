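# Methods

## Problem and model

During percutaneous cryoablation of a renal tumor, the interventionalist
aims for the frozen region (the "ice ball", visible on intraprocedural MRI)
to cover the MRI-visible tumor with a safety margin, conventionally 5 mm.
Given co-registered binary segmentations of the tumor (pre-ablation) and the
ice ball (post-ablation), the package quantifies the **minimal treatment
margin (MTM)**: the smallest signed 3D distance from the tumor surface to
the ice-ball surface. The margin at a tumor-surface point *p* is the ice
ball's signed Euclidean distance field sampled at *p* — positive when *p*
lies inside the ice ball, negative when it protrudes. The MTM is the minimum
over the surface; a negative MTM means incomplete coverage. The smallest
margin is localized anatomically by dividing the tumor into octants along
the patient left–right, anterior–posterior and cranio–caudal axes through
the tumor center of mass, and per-voxel coverage is classified into three
classes: covered with the intended margin, covered but insufficient, and
uncovered.

## Geometric conventions and numerical choices

* **World frame.** All geometry lives in RAS millimeters. NIfTI volumes in
  other orientations are reoriented on load so octant labels (R/L, A/P,
  S/I) are unambiguous. Voxel indices are 0-based; affines address voxel
  centers.
* **Distance convention.** The signed distance field is voxel-center to
  voxel-center: the magnitude at a voxel is the Euclidean distance (in
  world mm, anisotropic-spacing-aware) to the nearest voxel center of
  opposite membership. No sub-voxel surface is interpolated. This makes
  every value exactly reproducible by exhaustive all-pairs computation,
  which the test suite exploits as an oracle at small grid sizes. The cost
  is a resolution band: individual surface margins are biased upward by up
  to about one voxel (surface voxel centers sit inside the continuum
  surface; background centers sit outside it), and the MTM of sphere
  phantoms lands within roughly half a voxel diagonal of the closed form in
  typical geometry, with rare near-tangent configurations reaching about
  one voxel. Reports therefore carry `voxel_diagonal_mm`, and margins
  should be read as ± half a voxel diagonal.
* **Surface definition.** Tumor surface voxels are foreground voxels with
  at least one of six face-adjacent neighbors in the background
  (out-of-volume counts as background). On a digital sphere this
  6-connectivity shell counts roughly 0.75–0.8 × 4πr² voxels — a known
  property of face-exposure counting, not an error.
* **Rounding.** The reported integer MTM rounds half away from zero. The
  "intended margin achieved" flag is evaluated on the *raw* MTM (so 4.6 mm,
  which rounds to 5, does not count as a 5 mm margin achieved) — a
  deliberately conservative clinical reading.
* **Octants.** Axes are the fixed patient axes, not tumor principal axes;
  the origin is the foreground center of mass in world mm; exact-zero
  offsets go to the positive (R, A, S) side. Coverage fractions are volume
  fractions over tumor voxels, since surface areas are not defined under
  the voxel-center convention.
* **Resampling.** Masks are resampled with nearest-neighbor interpolation
  (labels cannot be averaged); rigidity of a supplied transform is enforced
  to 1e-6 on orthonormality and determinant.

## Registration

Pre/post co-registration is the closed-form weighted least-squares rigid
fit (Kabsch/Umeyama with scale fixed at 1) on corresponding anatomical
landmarks (cysts, renal cortex, local vasculature near the tumor), with a
reflection guard that flips the smallest singular direction if the optimal
orthogonal matrix is improper. Landmark weights (default uniform) let users
emphasize landmarks close to the treated region. A precomputed rigid
transform can be supplied as JSON instead; intensity-based and deformable
registration are out of scope. On noise-free rigidly related landmarks the
fit is exact to 1e-9; with 0.5 mm isotropic jitter on 10 landmarks in a
100 mm origin-centered box, the translation is recovered within 0.6 mm in
over 95% of trials.

## Cohort statistics

Per-case records (diameter, volumes, margin, sex, ASA class, renal
complexity category, progression status, follow-up months) feed the
classical battery:

* Mann–Whitney U (exact by enumeration when n₁·n₂ ≤ 400 with no ties, else
  normal approximation with tie and continuity corrections).
* Fisher's exact 2×2 and the Freeman–Halton r×c generalization, both by
  full enumeration over tables with the observed margins under the
  multivariate hypergeometric null, two-sided by the probability method
  (sum of probabilities ≤ the observed table's, with 1e-7 relative slack
  for float ties) — the convention of mainstream statistical software.
  Exact enumeration is bounded at r·c ≤ 12 and N ≤ 200; beyond that a
  seeded Monte-Carlo estimate (default 100 000 margin-preserving draws,
  add-one corrected) is available.
* Spearman rank correlation with the t-approximation p-value (df = n − 2).
* Univariable Cox proportional hazards, maximized by Newton–Raphson on the
  Breslow-ties partial likelihood (Efron switch available), convergence at
  1e-9 relative log-likelihood change, max 100 iterations. Tumor diameter
  enters per cm, margins per mm. Hazard ratios carry Wald 95% intervals.
  A monotone likelihood (perfect separation) is detected by the coefficient
  escaping |β| ≥ 15 and reported capped with a divergence warning rather
  than as a converged estimate.
* Kaplan–Meier progression-free survival (right-continuous product-limit,
  via lifelines) evaluated at 12 and 24 months.
* Group medians use inclusive quartiles (Tukey hinges).

Independent cross-checks in the test suite: scipy's `fisher_exact`
(exhaustive scan over small tables), R's `fisher.test` (frozen value for a
3×3 table), lifelines' `CoxPHFitter` on tie-free simulated cohorts (where
Breslow and Efron coincide), and hand-derived closed forms (a three-subject
Cox design with interior maximum β = −ln 2 ⁄ 2; a four-subject
Kaplan–Meier).

## Synthetic data

**Phantoms.** Ellipsoid pairs voxelized on a shared lattice (a voxel is
foreground iff its center is inside). For sphere pairs the true MTM has the
closed form r_ice − |offset| − r_tumor, valid through tangency and full
disjointness; for general ellipsoids the truth is brute-forced by sampling
10⁵ near-uniform directions (golden-angle spiral) on the tumor surface and
taking nearest distances to an equally dense ice-surface sample (doubling
the sampling moves the value by < 0.01 mm). A sweep generator produces
sphere pairs whose analytic margins span −11 to 6 mm — the clinically
observed range — with tumor radii 8–13 mm and ice radii 6–8 mm larger,
on a 96³ grid at 1 mm isotropic spacing.

**Cohorts.** The generator emulates the summary structure of a small
renal-cryoablation series: tumor diameters truncated-normal (mean 31.3 mm,
SD 9.4, bounds 16–51 mm — note the asymmetric truncation raises the
realized mean to ≈ 31.9 mm); margin mtm = 9 mm − 2 (mm/cm) · diameter_cm +
N(0, 2.5 mm), which builds in the inverse size–margin association and
places negative margins predominantly above 3 cm; progression events from
an exponential proportional-hazards model with log-hazard −0.26 per mm of
margin; administrative censoring uniform on 1–58 months; sex/ASA/renal
frequencies 0.666 / 0.566 / (0.625, 0.344, 0.031). The baseline hazard,
0.008 events/month at 0 mm margin, was chosen once so a 32-case cohort
yields roughly a 19% progression frequency under this censoring. The
generator returns its true parameters so tests can check recovery (Cox CI
coverage of the true hazard ratio at the nominal rate; Kaplan–Meier against
the analytic survival mixture). These defaults are a qualitative stand-in
for the real series, not estimates of it: the generator does not model
per-case segmentation error, correlated covariates, informative censoring,
or multi-probe ice-ball shape, so passing tests demonstrate correctness of
the estimators under the stated model, not clinical validity.

## Problem sizes

The test suite and the acceptance script run phantoms at 64³–96³ voxels
(1 mm isotropic), brute-force oracles at 5³–6³, cohort simulations at n =
32–10 000, and 100-seed replications for coverage-type checks; these sizes
give stable verdicts for every property tested while keeping runs desk-scale.

## Known limitations

* Margins are voxel-center quantities; sub-voxel accuracy requires finer
  acquisition, not post-hoc interpolation (halving the spacing halves the
  error band).
* Masks touching the volume boundary make the outside distance field
  unknowable beyond the field of view; such masks are accepted with a
  warning.
* Concave ice balls: the signed-distance reading of a negative margin
  (distance to the nearest ice *boundary*) coincides with
  distance-to-the-surface for convex ice balls but can differ for concave
  ones; the signed-distance reading is what is implemented.
* Only univariable Cox is provided; the cohort sizes this targets cannot
  support multivariable models.
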