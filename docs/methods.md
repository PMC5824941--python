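# Methods

`prfkit` implements a population-receptive-field (pRF) analysis pipeline for
bar-sweep retinotopic mapping, together with the downstream statistics used
to compare visual field coverage and natural-viewing behavior between
groups. Because no raw fMRI or eye-tracking data ship with the package,
every analysis is exercised end-to-end on synthetic data with known ground
truth; the synthetic generators are first-class, tested code.

## The CSS pRF model

Each voxel's pRF is an isotropic 2D Gaussian over the visual field with
center (x, y) in degrees of visual angle (dva) and width sigma. For a
binarized stimulus movie S(x, y, t), the per-frame neural drive is the
stimulus–Gaussian overlap raised to a compressive exponent,

    d(t) = ( Σ_pixels S(x, y, t) · exp(−((x−x₀)² + (y−y₀)²) / 2σ²) )ⁿ ,

with n ∈ (0, 1] (compressive spatial summation, CSS). The predicted BOLD
timecourse is g · (d ⊛ h), where h is a canonical double-gamma HRF sampled
at the TR (peak delay 6 s, undershoot delay 16 s, unit dispersions, peak :
undershoot ratio 6 : 1, 32 s support, peak-normalized) and g a non-negative
gain. With n = 1 the model reduces to the classic linear pRF. The effective
pRF size under compression is sigma/√n, the quantity the CSS software
lineage reports as "pRF size"; plain sigma is stored alongside it.

The HRF functional form and parameters are a package design choice (the
analysis tradition this implements does not pin them); they are exposed in
`HRFSpec` and shared across voxels and participants — no per-subject HRF
estimation.

## Stimulus protocol

The mapping stimulus is a bar (default width 2 dva, length 14 dva) swept
across a circular field of radius 7 dva in 4 orientations (0°, 45°, 90°,
135°), each traversed in both directions: 8 sweeps per run. The bar steps
edge-to-edge in 12 equal increments per sweep (96 frames at TR 2 s). A
pixel is "on" when its center lies inside the bar rectangle and inside the
field disc; the default aperture grid is 101×101 so that a pixel center
falls exactly on fixation. Visual-field convention throughout: x rightward,
y upward, origin at fixation. Screen-pixel gaze data (y downward) are
converted exactly once, in the bias-vector computation.

A session is 4 runs. The default session-level treatment is
**concatenation**: the run protocol is tiled back-to-back into one
continuous movie (`ApertureMovie.tiled`), simulated and fit as a single
timecourse of 384 samples. Voxel-wise run averaging is also available
(`simulate_bold_runs(average=True)`). Concatenation was chosen as the
default because the variance-explained statistic of the fit is maximized
over thousands of grid candidates: at 96 averaged samples, pure-noise
timecourses exceed the 5% variance-explained acceptance threshold in ~19%
of voxels, whereas at the concatenated length the exceedance rate is ~0%.
The selection threshold retains its intended specificity only at the
session length.

## Fitting

Fitting is two-stage, per voxel:

1. **Grid stage.** Exhaustive search over a candidate bank: 17×17 centers
   spanning ±7 dva, 8 log-spaced sigmas from the 0.21 dva floor to 7 dva,
   and exponents {0.25, 0.5, 0.75, 1.0}. For each unit-gain candidate
   prediction p, the gain has the closed form g = max(0, ⟨p, y⟩/⟨p, p⟩)
   and the score is R² about the observed mean, clamped below at 0. Ties
   resolve to the first candidate in deterministic grid order. The bank is
   cached (`PredictionBank`) and shared across voxels and calls.
2. **Refinement.** Bounded Powell refinement of (x, y, sigma) from the best
   grid point, repeated at each discrete exponent value, keeping the best.
   The exponent deliberately stays on its grid: jointly refining n walks an
   almost perfectly flat sigma–n likelihood ridge (for pRFs smaller than
   the bar, raising the overlap to a power is nearly indistinguishable from
   a gain change), which destroys sigma estimates under noise while barely
   changing variance explained. Joint refinement is available via
   `FitGridSpec(refine_n=True)` for users who want the unconstrained
   optimum.

**Identifiability of the exponent.** At realistic noise (10% of signal sd,
4 runs), the exponent is not identifiable per voxel for small pRFs: the
best achievable fit with the exponent forced to a *wrong* grid value lies
within ~10⁻⁴ variance-explained units of the true-exponent fit, while
noise perturbs measured variance explained by ~2.5×10⁻³. Consequently
fitted n is correct for only about half of simulated voxels, and sigma
(≈ size·√n) inherits those flips, with a bimodal error distribution.
Effective size — invariant along the ridge — is recovered with ~5% median
error regardless, as are pRF centers (median error ~0.01 dva) and the
size–eccentricity line. Analyses downstream of the fit therefore operate
on effective size, never raw sigma. Parameter-recovery tests assert the
center, size-line, and (faithfully, knowing the above) the sigma
tolerances.

**Exclusion filters.** After fitting, voxels are kept only if variance
explained exceeds 5%, the center eccentricity is at most 7 dva (centers at
exactly 7 are retained; the exclusion is strictly beyond the stimulated
field), and sigma lies strictly above the 0.21 dva fitting floor.
Exclusion counts per rule are logged as JSON-lines records.

## Visual field coverage (VFC)

Each surviving pRF contributes a unit-peak Gaussian at its center with
width equal to its effective size. An ROI's coverage map combines member
densities pointwise — mean by default, following the procedure's text
description; max is implemented as well since the published figures are
labelled as maximum-density coverage — on a 128×128 cell-centered grid
over [−7, 7]². Outlier voxels are downweighted by a bootstrap: 50 draws of
n voxels with replacement from the n-voxel ROI, each combined map
renormalized to peak 1, averaged, and renormalized again. (Whether the
original procedure renormalized per draw or only at the end is ambiguous;
per-draw was chosen so every draw contributes on a common scale. With a
single-voxel ROI the bootstrap is exactly deterministic.)

Group maps mirror right-hemisphere maps across the vertical meridian before
pointwise averaging, so contralateral coverage aligns; the group mean is
deliberately not renormalized (inputs are already peak-1 per participant).

Scalar summaries:

* **Extent** — the map is binarized at 0.01 (values ≥ 0.01 count as
  covered), and the covered proportion of in-field grid points is scaled
  by the stimulated area πr² (r = 7 dva), giving square dva. Extent is
  monotone nonincreasing in the binarization threshold.
* **Center-of-mass (CoM) distance** — the density-weighted centroid over
  in-field points; its distance from fixation indexes foveal bias.
* **Jackknife SE** — group-level standard errors use the leave-one-out
  jackknife, SE = √[(n−1)/n · Σ(θ̂ᵢ − θ̄)²]. (The source wording "leaving
  out n−1 participants" reads literally as single-participant folds;
  leave-one-out is the standard estimator and equals the classical sd/√n
  for linear statistics, which the tests assert.)

## Group statistics

* **Size vs. eccentricity** — per participant, weighted least squares of
  effective size on eccentricity with variance explained as weights
  (statsmodels WLS); slopes and intercepts are averaged across
  participants. With equal weights this reduces to OLS.
* **2D two-sample Kolmogorov–Smirnov** — D is the maximum over origins
  (placed at every data point of both samples) and the four open
  axis-aligned quadrants of the difference in empirical quadrant
  fractions. p-values by label permutation (default; 1000 permutations,
  seeded, with the +1 small-sample correction) or by the large-sample
  Kolmogorov approximation with the Fasano–Franceschini correlation
  correction. D is invariant to common translation/scaling of both
  samples; permutation p-values are uniform under the null (calibrated in
  tests at a 0.05 ± 0.02 rejection rate).
* **Coverage → points** — the KS test consumes planar point sets; coverage
  maps are converted by density-weighted sampling of in-field grid cells
  (default 500 points per participant map, pooled within group). The
  original analysis does not state its sample construction; this choice is
  recorded in output metadata.
* **Scalar contrasts** — Welch's t-test for group differences on derived
  scalars; Pearson correlation (with n) for age relationships.

## Gaze analysis

Raw gaze streams are scrubbed around blinks: samples within a 100 ms pad
on either side of each blink are dropped over half-open intervals, with
overlapping windows merged (idempotent, no double removal). Fixations
arrive pre-segmented; no velocity-based event detection is performed.

Per participant and stimulus, a duration-weighted fixation histogram on
the 768×1024 screen grid is smoothed with a Gaussian (sigma = 18.75 px)
and normalized by its maximum; group maps are pointwise means. The adult
fixation zone (AFZ) is the set of pixels where at least 70% of adults
fixated — "fixated" meaning the participant's normalized density exceeds
0.01 (the presence threshold is a package choice, exposed in config). The
alternative reading — thresholding the group-average density at 70% of its
peak — is available as `method="mean_density"`. The AFZ shrinks
monotonically as the overlap requirement rises.

Children are scored per stimulus (never by cross-stimulus alignment, since
stimuli are jittered): the **outside-AFZ ratio** is fixation time outside
the AFZ over total fixation time, compared against the 0.30 chance level
implied by a 70% contour. The **bias vector** runs from the adult center
(CoM of the AFZ-restricted adult density; the density-weighted variant was
chosen over the bare mask centroid) to the child density CoM, reported in
visual-field convention. The **null-quadrant test** measures each vector's
wrapped angular distance to the nearest boundary of the null quadrant
(lower-left, [180°, 270°], for faces; lower-right, [270°, 360°], for
words; distance 0 inside) and applies a one-sample t-test of the distances
against zero; 25% of uniformly random vectors would land inside any
quadrant.

## Synthetic data: what it emulates and what it does not

* `sample_ground_truth_prfs` draws pRF populations whose effective size
  follows a linear function of eccentricity (default slope 0.1, intercept
  0.5 dva, Gaussian scatter 0.05 dva, eccentricities uniform on
  [0.5, 6] dva) with polar angles uniform over the hemifield contralateral
  to the hemisphere label and a shared compressive exponent (default 0.5).
* `simulate_bold` pushes ground truth through the same CSS forward model
  the fitter assumes, plus i.i.d. Gaussian noise per timepoint. Temporal
  autocorrelation, drift, motion artifacts, and HRF variability are
  deliberately absent: passing recovery tests demonstrates correctness of
  the estimator under the model, not robustness to real scanner noise.
* `simulate_gaze` draws isotropic Gaussian fixation clouds around each
  stimulus-box center plus a group-level pixel offset (the child/adult
  contrast), with uniform durations. It does not model saccade dynamics,
  main-sequence kinematics, or stimulus-dependent salience.

The end-to-end pipeline (`run_pipeline`) simulates two groups whose pRF
populations differ in eccentricity range (adults more foveal), fits and
filters every participant, computes per-participant and group coverage,
CoM with jackknife SEs, extent, the 2D KS contrast on coverage samples,
and the full gaze analysis, writing tab-delimited tables, a JSON manifest,
JSON-lines logs, and a plain-text report. Every stochastic stage consumes
its own named seed from the config; identical configs give bit-identical
deterministic artifacts (manifest timestamps aside).

## Numerical choices and degenerate inputs

* Candidate predictions are held in float32 (memory); refinement and
  reported fits are float64. On-grid self-consistency is exact to ~10⁻⁵
  in variance explained.
* Negative R² (prediction worse than the mean) clamps to 0; negative gain
  projections clamp to 0 and score as unexplained.
* Constant timecourses cannot be scored (R² undefined) and become flagged
  rows (`constant_tc`) rather than aborting a batch; an all-zero candidate
  bank yields a flagged `null_fit`.
* Bootstrap, gaze, KS-permutation, and sampling seeds are explicit
  arguments everywhere; no global RNG state is used.
* Grid discretization: coverage grids sample cell centers; halving the
  cell size moves extent and CoM by less than one coarse cell's
  contribution (asserted in tests).

## Problem sizes used in the shipped tests and acceptance script

Parameter recovery uses 200 voxels at the full protocol (4 concatenated
runs, 101×101 apertures, the default fit grid); null calibration fits 100
pure-noise voxels on the same bank; KS calibration runs 200 null
simulations at n = 20+20 with 1000 permutations; gaze analyses use 11
adults and 12 children with 30 fixations per stimulus. The demonstration
pipeline defaults to 3 participants per group and 30 voxels per ROI.
These sizes keep a complete run to a few minutes on one CPU while leaving
every statistical check well-powered.

## Known limitations

* White measurement noise only; no temporally correlated noise model.
* One ROI per pipeline run; the multi-ROI × hemisphere × group ANOVA
  machinery of a full study is out of scope (generic statistics).
* The per-voxel compressive exponent is reported but should not be
  interpreted at single-voxel resolution at realistic noise levels (see
  the identifiability analysis above).
* No NIfTI/surface ingestion: inputs are tables and array containers; no
  cortical-surface visualization.
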