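# prfkit

Population receptive field (pRF) modeling and visual-field-coverage
statistics for bar-sweep retinotopic mapping, plus the eye-tracking
analyses used to relate coverage to natural viewing behavior — exercised
end-to-end on synthetic data with known ground truth.

## Who this is for

Visual neuroscientists who want a tested, reproducible reference
implementation of the compressive spatial summation (CSS) pRF pipeline and
its downstream group statistics: coverage bootstrapping, hemifield-flipped
group maps, coverage extent and center-of-mass (CoM) foveal-bias measures
with jackknife errors, a two-dimensional two-sample Kolmogorov–Smirnov
test, and fixation-density / adult-fixation-zone / bias-vector analyses of
free-viewing gaze data. Since raw study data of this kind are rarely
shared, the package includes synthetic generators that emulate the whole
measurement chain, so every stage can be validated against ground truth.

## The model

A voxel's pRF is a 2D Gaussian with center (x, y) and width σ (degrees of
visual angle, dva). Given binary stimulus apertures S(x, y, t), the
predicted BOLD signal is

    r(t) = g · [ ( Σ_{x,y} S(x, y, t) · G_{x₀,y₀,σ}(x, y) )ⁿ ⊛ HRF ](t)

with compressive exponent n ∈ (0, 1] and gain g ≥ 0; effective pRF size is
σ/√n. Fitting maximizes variance explained (R² about the mean) by grid
search over (x, y, σ, n) with the gain solved in closed form, followed by
bounded refinement. Voxels survive to analysis only with variance
explained > 5%, eccentricity ≤ 7 dva, and σ above the 0.21 dva floor.
Coverage maps combine unit-peak Gaussians of the surviving pRFs
(bootstrapped 50×, peak-normalized per participant). See
`docs/methods.md` for the complete account, including why the exponent —
and therefore raw σ — is not identifiable per voxel at realistic noise,
while effective size is.

## Worked example

Run the demonstration study — two synthetic groups ("children" and
"adults") whose pRF populations differ in how foveal their coverage is,
plus a gaze experiment with a configured child fixation bias:

```
prfkit run --out-dir out/demo
cat out/demo/report.txt
```

With the default configuration and seeds this prints:

```
prfkit synthetic study report
================================

Stimulus: 8 sweeps, 96 frames, TR 2.0 s, field radius 7.0 dva

Coverage statistics by group (CoM distance in dva, extent in square dva; size-ecc line averaged across participants):
   group  n  com_mean  com_jackknife_se  extent_mean  slope_mean  intercept_mean
children  3  2.122965          0.196186   126.231899    0.253235        0.779505
  adults  3  1.618090          0.150209   105.101042    0.268754        0.756315

2D KS (children vs adults coverage): D = 0.218, permutation p = 0.0020 (n = 600 vs 600 sampled points)
Welch t-test on CoM distance: t = 2.04, p = 0.1153

Gaze analysis (synthetic children vs adults):
  mean outside-AFZ ratio in children: 0.269 (chance 0.30)
  bias vector stim00: angle 46.4 deg, magnitude 66.2 px
  bias vector stim01: angle 38.8 deg, magnitude 49.5 px
  null-quadrant test (lower-left): t = 54.57, p = 0.0117
```

Reading the numbers: the adult group's coverage center of mass sits 1.62
dva from fixation versus 2.12 dva in children — the configured foveal-bias
contrast — with leave-one-out jackknife standard errors; the 2D KS test
detects the coverage difference (D = 0.218, permutation p = 0.002). In the
gaze experiment the children were simulated with a (+40, −40) screen-pixel
fixation offset, and the recovered bias vectors point into the upper-right
visual-field quadrant (angles 46° and 39°) with magnitudes near the
configured offset; their angular distances from the lower-left null
quadrant are significantly nonzero.

Individual stages are available as library functions
(`generate_bar_apertures`, `simulate_bold`, `fit_population`,
`filter_fits`, `roi_coverage`, `ks2d_two_sample`, `fixation_density`, ...)
and as CLI subcommands (`simulate-stim`, `simulate-bold`, `simulate-gaze`,
`fit`, `coverage`, `stats`, `gaze`, `run`, `report`).

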