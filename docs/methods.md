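# Methods

This note documents the models and numerical choices behind `hippofc`: what
each stage computes, what the synthetic-data generator does and does not
emulate, and where the design was genuinely open.

## Volumetry and neuropsychology

The asymmetry index QAI = 1 − min(VLH, VRH)/max(VLH, VRH) is recomputed
from the raw volumes at full precision; the bundled table's printed QAI
column is rounded to 2 decimal places for two of the three groups and is
never used in statistics.

All group comparisons use the **pooled-variance** two-sample t-test
(df = n1 + n2 − 2), which exactly reproduces the published t-scores from
the bundled per-subject data; Welch's test is available via
`equal_var=False`. Missing neuropsychological scores are excluded
per-measure (each measure keeps every subject that has it), which matches
the published degrees of freedom (n = 8 + 8 for most measures, 7 + 7 for
verbal fluency). Degenerate inputs are handled explicitly: zero pooled
variance with equal means gives t = 0, p = 1; with unequal means an
infinite-t sentinel with p = 0.

One caveat is intentional: the QAI rows of the published comparison table
do not agree with any t-test recomputable from the published volumes
(recomputation gives −4.99 / −3.20 / 0.81 where −5.33 / −3.18 / 0.85 are
printed; the first duplicates the adjacent volume t-score and looks like a
typesetting slip). The report prints the recomputed values; the
reproduction tests assert only the volume t-scores, which match to 2
decimal places.

## Preprocessing

Order: discard the first `n_discard` volumes (default 5; a 185-volume run
at TR = 2 s becomes 180 frames), smooth, band-pass.

**Smoothing** is a separable spatial Gaussian applied frame by frame, with
per-axis sigma = FWHM / voxel_size / (2√(2 ln 2)) in voxels (default FWHM
6 mm) and reflection at the grid edges, so constant images are preserved
and small synthetic grids show no intensity falloff.

**Band-pass** (default 0.01–0.08 Hz) is an orthogonal projection in the
time domain: a rectangular DFT mask keeping frequencies strictly inside
(f_lo, f_hi) — DC always removed, so the filter demeans — composed with
exact removal of the in-band span of constant and linear trends. The
polynomial term exists because a finite drift ramp is not periodic: its DFT
leaks roughly 15 % of its variance into the pass band, and a pure mask
would leave up to 95 % of the ramp's amplitude in place near the run edges.
Projecting out the in-band linear-trend direction removes ramps exactly
while keeping the operator a projection — linear and idempotent to machine
precision. Detrending order 1 (the usual default for resting-state
band-pass tools) was chosen over higher orders deliberately: order 3
attenuates a 0.04 Hz probe sinusoid visibly (correlation with input drops
to 0.987), order 1 keeps it at 0.995. Residual quadratic/cubic drift after
filtering is below 10 % of its input sd, which is negligible against the
in-band noise floor. A 4th-order zero-phase Butterworth variant
(`filter_method="butterworth"`) is provided for real-data use; it is not a
projection and is not used by the generator.

At T = 180, TR = 2 s the projection keeps bins k = 4..28 (two real
dimensions each) minus the one detrend direction: 49 of 180 dofs, so white
noise of variance σ² retains variance σ²·49/180 ≈ 0.27 σ². This dof
accounting (`band_dof`) feeds the closed-form oracle below.

## Synthetic cohort generator

The generator produces what the imaging stages need and nothing more: 4D
volumes on a toy atlas, already aligned on a common grid (no motion,
no slice timing, no scanner physics, no hemodynamic convolution).

**Toy atlas** (default): a 32×32×16 grid of 2 mm isotropic voxels (so 125
voxels = 1 cm³ exactly), an ellipsoidal brain mask (~7100 voxels), two
mirrored spherical hippocampus ROIs of radius 2 voxels (33 voxels each) and
around each a radius-5 ipsilateral network sphere (~500 voxels). The affine
puts x = 0 on the midsagittal plane, matching the MNI sign convention
(negative x = left).

**Signal model.** Per run, two hemisphere latents are built by drawing
white Gaussian pairs correlated at ρ_lr, pushing them through the same
band-pass projection used in preprocessing (so the planted signal survives
filtering by construction), and standardizing to unit sample variance.
Every coupled voxel (ROI + network, per hemisphere) receives

    ρ · latent + √(1 − ρ²) · idiosyncratic

with unit-variance band-limited idiosyncratic noise, and every brain voxel
additionally receives a baseline of 100, a random cubic polynomial drift
(Legendre basis, coefficient sd = `drift_amp`, default 1) and white noise
of sd `noise_sd` (default 1). All randomness descends from one integer
seed through per-(group, subject, run) seed sequences — the group label
enters the key so groups are independent even under a shared master seed —
and cohorts are bit-reproducible, including file checksums.

**Group defaults.** The published effect sizes for connectivity are
unknown, so the couplings are illustrative and were fixed once from the
variance decomposition below, to plant the condition's qualitative
hierarchy — controls strongest, right-MTLE intermediate, left-MTLE weakest
in *both* hemispheres (the modelled condition's key feature is that
left-sided disease is worse even for the contralateral seed):

| group | ρ left | ρ right | ρ_lr |
|---|---|---|---|
| control | 0.70 | 0.70 | 0.40 |
| right MTLE | 0.60 | 0.55 | 0.15 |
| left MTLE | 0.40 | 0.45 | 0.10 |

Desk-scale default cohort: 9 subjects per group, 2 runs × 185 volumes
(10 runs are supported; 2 keep a full three-group analysis near ten
seconds). The volumetry generator draws per-subject volumes from the
cohort's published group means/sds, truncated at zero.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: physiological noise spectra (cardiac,
respiratory aliasing), motion artifacts, spatial autocorrelation of real
BOLD noise (white off-network noise makes Bonferroni correction exact
rather than conservative), inter-subject anatomical variability, and
hemodynamic response shape.

## Connectivity and group inference

The seed is the unweighted mean series over the ROI mask. Pearson r per
brain voxel; zero-variance voxels are undefined (NaN) and excluded
everywhere downstream, never set to r = 0. Negative correlations are
zeroed. The subject-level p < 1e-4 threshold is recorded as an r cutoff
(inverse t CDF at df = n−2); by default it is *not* applied before group
entry — zero-filled hard-thresholded maps distort group t statistics — but
the literal thresholded variant is a flag (`hard_threshold=True`).

Two z definitions are offered because "Fisher z applied to t-values" is not
a well-defined operation (arctanh needs |·| < 1): the default reads the
step as the standard Fisher transform z = arctanh(r); the alternative
`t_to_normal` Gaussianizes t through its CDF, z = Φ⁻¹(F_t(t; n−2)), with
quantiles clipped at ±8. Both are strictly increasing in r, so they rank
voxels identically. Runs aggregate by voxelwise mean of per-run z maps
(Fisher-z averaging); concatenation before correlation is an option.

Group maps: one-sample t = mean/(sd/√n), df = n−1; two-sample pooled t,
df = n1+n2−2; both propagate NaN and map zero variance to ±inf sentinels
(0 where the mean is also zero). Voxel thresholding is one-sided on
positive t (connectivity maps are positive after negative removal, and
intergroup hypotheses are directional); "corrected" means Bonferroni over
in-mask defined voxels — conservative and assumption-free; random-field or
permutation corrections are out of scope. Cluster decomposition uses
18-connectivity by default (6 and 26 selectable), eliminates components
below 125 voxels (strictly: 124 is removed, 125 retained), and reports per
cluster its size, peak t and peak coordinate in grid and world (mm) frames.

The asymmetry summary counts voxels with t strictly above the display
threshold (default 6, matching the strict "T > 6" convention; ties at
exactly 6.0 are excluded) per (seed, contrast), bins them in right-open
0.5-t-unit bins from the threshold (the original figure's binning is not
numerically specified), and infers the group ordering from which patient
group loses more voxels against controls. Contrasts are one-sided
control-minus-patient (and right-minus-left MTLE), following the
"in favor of" reading of the intergroup comparisons.

## Validation strategy and the calibration caveat

The published imaging numbers (t_max values, cluster sizes, the
630/6494/1765/8232 suprathreshold counts) are not reproducible — the scans
were never deposited — so the imaging stages are validated by properties
with known answers:

- **Null calibration.** On white-noise subjects the one-sided p < 1e-4
  voxel rate must sit within 3 binomial sds of 1e-4, and Bonferroni-
  corrected group maps over 100 null cohorts must yield essentially zero
  suprathreshold voxels. Two subtleties are deliberate. First, the
  calibration run uses no band-pass and no smoothing: the parametric
  p-value with n = time points assumes temporally white data, and 0.01–0.08
  Hz filtering reduces the effective dof from 178 to ~49, inflating the
  tail rate by orders of magnitude. The convention of using n = time points
  on filtered data is field-standard (and is what the method being
  reproduced states), but it is a display convention, not a calibrated
  error rate — a documented limitation. Second, the seed's own mask voxels
  are excluded from the count: each correlates with the mask average at
  about 1/√m ≈ 0.17 by construction.

- **Closed-form recovery.** After band-passing, drift vanishes and the
  expected seed-to-network-voxel correlation has the closed form

      r = ρ² / √( (1 + ν_f) · (ρ² + ((1 − ρ²) + ν_f)/m) ),

  with m the seed-mask voxel count and ν_f = noise_sd²·band_dof/T the
  in-band white-noise variance. At ρ = 0.7, m = 33, T = 180 this gives
  r ≈ 0.60 (z ≈ 0.70); the empirical mean subject z over network voxels
  (10 runs) must match within ±0.1. These checks run without smoothing,
  which is outside the closed form (smoothing pools neighbouring voxels'
  idiosyncratic noise and drives in-network correlations toward 1).

- **Ordering recovery.** Twenty independently seeded default cohorts; in at
  least 95 % the control-vs-left-MTLE suprathreshold count must exceed the
  control-vs-right-MTLE count for both seeds. With the default couplings
  the expected two-sample t at network voxels is ≈ 7 (ctrl − right) versus
  ≈ 11 (ctrl − left), so the ordering is recovered in practice in every
  replicate.

- **Oracle equivalence.** Pearson r, the pooled t (statistic, df and
  p-value) and connected-component labeling are each checked against
  independently coded brute-force implementations (textbook formulas,
  exhaustive flood fill) to 1e-12 / exactly.

Problem sizes throughout (32×32×16 grid, 2 runs default, 20 ordering
replicates, 100 null seeds) are the package's desk-scale choices: large
enough for the binomial/Poisson tolerances above to bite, small enough
that the full suite runs in a few minutes on one CPU.

## Known limitations

- Bonferroni over in-mask voxels is exact for the generator's white
  off-network noise but conservative on spatially smoothed or real data.
- The subject-level p < 1e-4 threshold's nominal rate does not hold on
  band-passed data (see above); the default pipeline treats it as map
  metadata rather than a pre-group-entry filter.
- The generator's group couplings are illustrative; only qualitative
  (ordering-level) conclusions transfer.
- Slice-timing, motion correction and spatial normalization are absent by
  design: synthetic data are generated aligned.
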