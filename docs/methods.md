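# Methods

## The RSNR statistic

For one acquisition the signal-to-noise ratio is computed over the
automatically segmented left-ventricular myocardium:
`SNR = mean / SD` with the *sample* standard deviation (n−1 denominator —
with VOIs of ~1–2 thousand voxels the choice is numerically negligible, but
it is fixed so results are exactly reproducible). The diagnostic marker is
`RSNR = SNR_stress / SNR_rest`; both acquisitions are segmented
independently so that repositioning between the rest and stress scans does
not couple the two VOIs. SNR is scale-invariant, so global count-scale
differences (dose, decay, acquisition duration) cancel within each
acquisition and the RSNR responds to the *count statistics*, not to the
display scaling. Classification is strict: RSNR < cutoff is positive, the
boundary value is negative; the default cutoff is 0.94.

The statistic is computed on native axial volumes. Short-axis reorientation
is unnecessary because mean and SD over a VOI are orientation-invariant.
No attenuation or scatter correction is modeled anywhere.

## Segmentation by spatial normalization

Sex-specific templates are built from normal rest studies: every volume is
registered to one explicitly chosen reference subject (default index 0),
resampled to its grid, and averaged voxelwise. The template LV mask is the
set of voxels above the Otsu threshold of the template histogram, restricted
to the largest 26-connected component. Two conventions had to be fixed where
the procedure is genuinely open:

* the Otsu histogram is computed over voxels above 1 % of the maximum, so
  the empty background does not swamp the two-class criterion;
* when several bin boundaries tie for the maximal between-class variance
  (the criterion is exactly flat across empty gaps between well-separated
  modes), the midmost maximizing boundary is returned. The lowest-boundary
  alternative puts the threshold at the left edge of the gap, is sensitive
  to floating-point summation order, and splits a clean bimodal sample far
  off-center.
* thresholding is volumetric (not slice-wise), with the largest-component
  rule guarding against extra-cardiac islands.

A subject is segmented by registering its volume (moving) to the sex-matched
template (fixed) and warping the template mask back through the inverse
transform (trilinear interpolation, binarized at 0.5). An empty warped mask
is treated as a registration failure, not silently accepted.

## Registration

Similarity is normalized cross-correlation — invariant to the global count
scale, which differs between rest and stress by design. Both inputs are
pre-smoothed by 8 mm FWHM to stabilize the cost surface on noisy count
images. Optimization is fully deterministic (geometric-center
initialization, fixed iteration budgets, regular — not random — metric
sampling with a fixed seed) so segmentation is reproducible run to run.

Three stages, all through SimpleITK:

1. **Rigid (Euler)**, multi-resolution at the coarse levels only
   (shrink 4/2, smoothing 12/8 mm FWHM), 300 iterations with a tight
   gradient-magnitude tolerance (1e-8). The rotational valley of a smooth
   blurred blob is extremely shallow (a few-degree error changes NCC in the
   third decimal), so the default optimizer tolerances stop far from the
   optimum; resolving the pose before releasing scales prevents the affine
   stage from absorbing rotation into shear.
2. **Affine (12-parameter)** over all levels (4/2/1, smoothing 12/8/4 mm),
   20 iterations, 50 % regular sampling.
3. **Optional coarse B-spline** (3×3×3 control-point mesh — the low mesh
   density is the smoothness regularizer — single level at shrink 2,
   L-BFGS-B). Off by default: on the ellipsoid-shell phantoms it improves
   NCC only in the third decimal while costing ~10× the affine stage on one
   CPU. It remains available through `RegistrationConfig(deformable=True)`
   and is exercised by the tests, including displacement-field inversion.

The achieved similarity is compared against the initializer's; if an
optimizer run degrades it, the initializer is kept and the result flagged.
Affine transforms invert analytically; deformable transforms invert by
iterative displacement-field fixed-point inversion, with the composition
residual checked to stay below half a voxel on average over the LV.

## The phantom

The left ventricle is a half-ellipsoid shell: inside the epicardial
ellipsoid, outside the endocardial one, on the apex side of the base plane
(apex capped, base open). Defaults: epicardial semi-axes 33/33/47 mm,
endocardial 22/22/36 mm → an 11 mm wall and a ~71 mL shell, about 1100
voxels at 4 mm. The long axis is tilted 40° from the grid axes, as in
clinical axial acquisitions, so reorientation/registration is non-trivial.
Expected counts: wall 18, blood-pool cavity 6, background 2 counts/voxel.
Optional regional defects carve angular sectors of reduced wall uptake.

Reconstruction is emulated as *blur-then-noise*: the expected-intensity
field is blurred by an isotropic Gaussian (7 mm FWHM default) and
independent per-voxel Poisson draws are taken from the blurred expectation.
This keeps the per-voxel variance equal to the local mean — the
count-dependence of SNR that the method exploits — which a noise-then-blur
model would largely destroy (smoothing a white Poisson field suppresses its
variance ~30-fold at these settings and the SNR would barely respond to the
stress count-scale). A variance-0 mode returns the expectations themselves
for exact tests. The stress acquisition scales all expected counts by the
stress factor `f` and re-poses the heart by a rigid jitter (up to 5°, 6 mm
by default).

The wall uptake of 18 counts/voxel was chosen so that (i) the resting shell
SNR is ≈ 3.3, close to clinically reported values (~4), and (ii) Poisson
variance and partial-volume "structure" variance inside the VOI are of
comparable size. The second point is essential: the structure component is
scale-invariant, so if it dominates (high counts) the RSNR saturates near 1
regardless of stress uptake and the clinical group distributions
(1.06 ± 0.17 vs 0.83 ± 0.15) are not reachable by any stress scale. At the
default the pipeline-measured RSNR spans ≈ [0.37, 1.37] for f ∈ [0.08, 8].

## Cohort calibration

`RSNR(f)` has no closed form under segmentation, blur and noise, so the
generator is calibrated empirically. The mean pipeline RSNR as a function of
f is fitted by Monte-Carlo: each calibration subject (geometry, sex and pose
drawn from the population) is segmented **once** by the full template
pipeline; its noise-free expectation fields and the two segmented masks are
then reused to evaluate every f knot, with the rest realization shared
across knots (rest does not depend on f) and stress counts redrawn as
Poisson(f·expectation). Fitting through the pipeline's own masks matters:
the warped template mask covers the blurred shell and is systematically
larger than the crisp geometric truth shell, shifting mean RSNR by up to
~0.05 at low f, so a truth-mask calibration would bias the cohort means.
Monotonicity is enforced on the fitted knots and the curve is interpolated
as log f against mean RSNR.

Per-subject stress scales are then drawn by inverting the curve at
per-subject target RSNRs sampled from the group distribution. Two
variance-control choices keep the *simulated study conditions* equal to the
*configured* ones:

* targets are stratified normal quantiles (randomly permuted), so the
  sample mean of each group's targets equals the group mean exactly;
* the target SD is deflated by the within-subject RSNR noise measured on
  the response curve, so the total simulated group SD (target spread +
  counting noise) matches the configured SD.

Covariates (age, BMI, sex mix) are drawn per group from the configured
normal/Bernoulli distributions; they do not influence image generation by
default. Male phantoms are 5 % larger, female 7 % smaller, so the two
templates genuinely differ.

## Evaluation statistics

* **ROC**: empirical curve over all distinct thresholds, trapezoidal AUC
  (equal to all-pairs concordance with half credit for ties); orientation
  auto-chosen so AUC ≥ 0.5 (RSNR and stress SNR come out lower-positive).
  The operating point maximizes Youden's J, ties broken toward higher
  specificity; reported cutoffs are midpoints between adjacent distinct
  scores, and classification at a cutoff is strict on the positive side.
* **Group comparison**: pooled-variance two-sample t-test by default, Welch
  optional.
* **Classifier comparison**: exact binomial McNemar on the discordant pairs,
  sensitivity on positives only, specificity on negatives only;
  p = min(1, 2·P(X ≤ min(b,c))), X ~ Bin(b+c, ½). With ~100 subjects the
  discordant counts are small, where the chi-square approximation is poor.
* **Univariate logistic regression** (maximum likelihood, Wald CI); markers
  that are lower in disease are negated so the odds ratio reads above 1.
  Perfect separation is reported as such, with no finite estimate.
* **Subgroup tables**: numeric covariates split at the cohort median (ties
  to the upper group), sex by category, metrics computed at the fixed
  whole-cohort cutoffs. Percentages are rounded to integers in report
  tables; raw values stay on the result objects.

## Problem sizes

The demonstration study and the acceptance script use a 48³ grid at 4 mm
(the phantom supports the native 70×70×50 acquisition matrix), 10 template
normals per sex, 40 calibration subjects and a 61 + 41 cohort — a complete
study runs in a few minutes on one CPU. The multi-seed replication of the
group t-test scores the replicate cohorts with the ground-truth-mask RSNR
(the full pipeline is exercised on the primary replicate); the truth-mask
statistic has slightly different group means but the same separation scale.

## What the phantom does and does not show

The generator reproduces the features the method depends on — count-
proportional noise, reconstruction blur, pose differences, sex-dependent
size, globally reduced stress uptake with optional regional defects — so
passing tests demonstrate that the pipeline recovers a known group contrast
through segmentation, noise and pose variability. It does not model
attenuation, scatter, respiratory/cardiac motion, extra-cardiac activity
(liver/gut), iterative-reconstruction noise correlations, or true anatomical
shape variability beyond affine size changes. Clinical performance numbers
(AUC, sensitivity at a fixed cutoff) therefore transfer only qualitatively;
in particular the simulated ROC operating point differs from clinical
reports because the simulated within-group spread is normal by construction.

## Known limitations

* Rotation about the LV long axis is nearly unidentifiable for the default
  circular-cross-section phantom (an ellipsoid of revolution); tests that
  check rotation recovery use unequal short axes.
* The affine registration tolerates the simulated pose scatter (≤ ~15°,
  ~12 mm); grossly mis-positioned acquisitions would need a broader
  initialization search.
* Only axis-aligned NIfTI volumes with positive voxel directions are read;
  DICOM/Interfile and gated series are out of scope.
* `calibrate_stress_scale` assumes mean RSNR is monotone in f, which holds
  for this noise model but is enforced, not proven, on the fitted knots.
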