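# Methods

This note documents the statistical models, the synthetic-data generator,
and the numerical/design choices behind `neoclaustrum`.

## ROI outcomes and the two control masks

All morphology runs in 0-based voxel index space on the integer label grid;
the NIfTI affine is carried for I/O fidelity but never used for
computation, and voxel anisotropy is ignored for structuring elements (the
intended resolution is 0.5 mm isotropic T2 space, where this is exact).

* **Absolute volume** of a label = voxel count × voxel volume (mm³).
* **TBV** = volume of every label except background, CSF, and ventricles;
  the brainstem is included.
* **Relative volume**: per side `V_side / TBV`; combined
  `(V_left + V_right) / TBV`. All other bilateral outcomes combine as the
  arithmetic mean of the two sides. These conventions are mutually
  consistent with published per-side and combined group values
  (e.g. mean(363, 357) = 360 mm³; 0.00098 + 0.00097 = 0.00195).
* **Claustrum frame** (white matter immediately around the sheet):
  "augmented by about two voxels on all sides" is implemented as Chebyshev
  dilation of radius 2 (two iterations of the 3×3×3 element — the literal
  "all sides" reading and the simplest reproducible choice), intersected
  with insular WM, minus every claustrum voxel. The radius is a parameter.
* **Claustrum-controlled** (interior): claustrum voxels whose
  26-neighbourhood (3×3×3 minus centre; out-of-bounds counts as
  non-claustrum) is at least 90 % same-side claustrum, i.e. ≥ 24 of 26.
  Whether the original criterion used the 26-neighbourhood or a larger
  sphere is not stated anywhere we could verify, so both the connectivity
  and the fraction are exposed as parameters and the strictest plain
  reading is the default.
* **ROI means**: arithmetic mean of the metric over mask voxels; an empty
  mask yields an explicit missing value (NaN), never 0. FA maps are
  clipped to [0, 1] on ingest with a logged count; MD is fixed at
  10⁻³ mm²/s at the I/O boundary. Metric maps must already be resampled to
  label space — a shape/affine check is enforced, resampling is out of
  scope.

Every extraction asserts the mask invariants (controlled ⊆ claustrum,
frame ∩ claustrum = ∅, frame ⊆ insular WM).

## Group statistics

* **GLMs** are OLS with the preterm group coded 1 (term 0) and sex coded
  male = 1. Rows with missing values in any used column are dropped per
  analysis with a logged count (diffusion outcomes legitimately have
  smaller n than T2 outcomes). Rank-deficient designs are rejected with
  the collinear terms named. Sums-of-squares type is irrelevant for these
  designs (one categorical + continuous covariates, 1-df terms).
* **Partial η²** for a 1-df term is `t²/(t² + df_resid)`, equivalent to
  `SS_term/(SS_term + SS_resid)`. The source analyses never state their
  formula; this standard choice reproduces their printed effect sizes from
  the printed group moments (see the acceptance suite).
* **Matching**: preterm subjects are processed in ascending scan age (ties
  by id); each takes the unused term control with the smallest absolute
  scan-age gap (ties: smaller control scan age, then smaller id). The
  processing order and tie-breaks are not documented in the source
  procedure; they are fixed deterministically so results are
  order-independent and reproducible.
* **Longitudinal models**: paired t-tests on second − first scans, and a
  linear mixed model with a single random intercept per subject fitted by
  REML (statsmodels MixedLM); fixed-effect p-values are Wald tests with no
  small-sample df correction — a documented approximation that is
  anti-conservative for very small subject counts.

## Structural covariance

Per (metric, side) family: Pearson r between the claustrum column and each
region column (pairwise-complete; zero-variance regions flagged missing),
Fisher z = atanh(r) with sample correlations clamped to ±(1 − 10⁻⁷) and a
logged count, then the two-independent-sample z test

    Z = (z_PT − z_FT) / sqrt(1/(n_PT − 3) + 1/(n_FT − 3)).

The source describes only "testing z-scores for significant differences";
this classical test is what the r-to-z step implies, and a bootstrap
alternative is deliberately out of scope. Benjamini–Hochberg correction is
applied across the regions of one (metric, side) family — the family
definition is ambiguous in the source and is therefore configurable.
Correlations are computed on raw metric values with no covariate
residualisation, matching the described procedure. Tissue-class summaries
report mean ± SD of z per class and `n_sig/n_total` counts
(34 cortical GM / 12 subcortical GM / 33 WM regions in the default
emulated parcellation).

## Synthetic cohort generator

The generator's defaults are the published study conditions; everything it
draws is Gaussian, the simplest model sufficient for moment- and
effect-size-recovery testing, since only means ± SDs are published.

* **Demographics.** Scan ages are truncated normals: term spectrum
  41.1 ± 1.7 (window GA 38–45), matched comparison 41.1 ± 1.7 for both
  groups (window GA 37.4–44.9, the published analysis window),
  longitudinal first scan 34.3 ± 1.9 and second 41.2 ± 1.5 weeks. Birth
  ages are free defaults (term 40.0 ± 1.2 truncated to 37–42; preterm
  32 ± 3 truncated to 24–36.9) since only group definitions are printed.
  Scan age is drawn first and birth age truncated below the subject's scan
  age; this guarantees scan ≥ birth while preserving the marginal
  scan-age (hence outcome) moments exactly, at the cost of a small
  downward bias in birth age. Sex is Bernoulli(0.5) with zero generative
  effect (it is only a covariate in the source analyses).
* **Outcomes.** `outcome = group mean + slope · (scan age − group mean age)
  + residual`. Specified SDs are *marginal* within-group SDs; the residual
  SD is `sqrt(SD² − slope²·var(scan age))` (using the truncated-window age
  variance), so generated moments match the specification exactly and
  effect-size recovery is well-defined. Per-side group means/SDs are the
  published Table-2 values; slopes are the published term-spectrum
  regression coefficients (volume 17.1/12.1 mm³/week right/left, MD
  −0.012/−0.014, FA 0.0050/0.0060).
* **Left–right correlation 0.9** (free default): published combined SDs
  (e.g. volume 51) approximately equal the per-side SDs (51/55), which is
  only possible if the sides are strongly correlated; ρ ≈ 0.9 makes the
  implied combined SDs match.
* **TBV** term 356,100 and preterm 369,200 mm³ are back-derived from
  combined volumes ÷ combined relative volumes (666/0.00187,
  720/0.00195); the SD (29,000 mm³) and the slope 17,000 mm³/week are free
  defaults, the slope chosen so the implied relative-volume trajectory
  matches the published −0.000048 per week. TBV is drawn independently of
  claustrum volume, so the *derived* relative-volume SD is slightly wider
  than the published one — relative volume is not a moment-recovery
  target.
* **Longitudinal model.** Two sessions share a subject-level random
  intercept; marginal moments are anchored at the second (term-equivalent)
  scan:
  `SD_marginal² = SD_intercept² + SD_resid² + slope²·var(age₂)`.
  Slopes are the published preterm mixed-model coefficients (mean volume
  16.6 mm³/week etc.). The within-subject intercept SD is unprinted and a
  free default (40 mm³ for volume, 0.025 for MD, 0.015 for FA,
  10,000 mm³ for TBV); the volume value implies a first-to-second-scan
  paired t ≈ 14 at n = 53, close to the published statistic — a
  consistency check, not a fit.
* **Regional tables.** One-factor model per region:
  `region = ρ·z(claustrum) + sqrt(1 − ρ²)·noise`, rescaled to a per-region
  mean/SD, so the population region–claustrum correlation is exactly ρ.
  Default ρ per tissue class and group is tanh(published mean z), e.g.
  cortical-GM MD: term tanh(0.40) ≈ 0.38, preterm tanh(0.08) ≈ 0.08.
  Region value scales are free defaults in plausible physiological ranges.
* **Phantom.** A schematic brain (default 64×64×48 voxels at 0.5 mm
  isotropic, the released T2 resolution): ellipsoid with CSF rim and
  cortical shell, ventricles, thalamus/caudate/lentiform spheres, a
  brainstem, and per side an insular-WM block containing a claustrum sheet
  (default 3 voxels thick) with a guaranteed ≥ 2-voxel insular margin.
  Geometry is deterministic given the spec; only voxel noise
  (free defaults: MD 0.02, FA 0.01) depends on the seed. Claustrum voxels
  carry the subject's tabulated MD/FA values, so noise-free extraction
  reproduces the table exactly — the round-trip oracle for the whole
  extraction stack. Tissue MD/FA means for the other labels are free
  defaults in neonatal ranges.
* **Control-analysis outcomes** (thalamus/caudate relative volume, GM and
  neighbour-region MD/FA, frame and controlled metrics as cohort columns)
  have free-default means/SDs chosen to be anatomically plausible and
  directionally consistent with the published control findings; only
  their analysis plumbing, not their values, is validated.

What the generator does **not** emulate: realistic anatomy or folding,
registration or segmentation error, scanner artefacts, non-Gaussian
outcome distributions, volume–TBV correlation, and any correlation
structure among regions beyond the shared claustrum factor. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated generative model, not robustness to real-data artefacts.

## Problem sizes and numerics

* Recovery runs use the published sample sizes (83/83 matched T2, 72/72
  diffusion, 377 term spectrum, 53 longitudinal); effect-size recovery
  averages 200 replicates and covariance-z recovery 50, which puts the
  Monte-Carlo SE of the reported means well below the comparison
  tolerances. Calibration suites (type-I error, FDR false-flag rate) use
  2000 replicates at reduced n (60 subjects; 15 regions) — calibration
  depends on the null, not on the full problem size.
* All randomness flows from `numpy.random.Generator`; replicate seeds are
  spawned from a single `SeedSequence`, making every result bit-reproducible.
* Degenerate inputs are errors, not silent results: empty claustrum labels,
  zero-variance paired differences, |ρ| ≥ 1, non-positive TBV, residual
  variance driven negative by a slope/SD combination, rank-deficient
  designs. Empty frame/controlled masks are allowed and flagged missing,
  since they can legitimately occur for thin sheets at coarse resolution.

## Known limitations

* Wald mixed-model inference (no Satterthwaite/Kenward–Roger correction).
* Greedy matching is not globally optimal (not an assignment-problem
  solver); it reproduces the described iterative procedure.
* The emulated 79-region parcellation carries generic region names; real
  Draw-EM label tables can be supplied as a YAML scheme but no bundled
  mapping is shipped.
* No image resampling or registration: inputs must be voxel-aligned.
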