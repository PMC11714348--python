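# Methods

## The embedding objective

The package fits a supervised linear embedding of a voxels × conditions
matrix of standardized GLM beta coefficients. Standardization z-scores
each condition column across voxels with the sample (n − 1) standard
deviation; this puts feature weights on a common scale so they are
comparable across conditions in weight plots. (The alternative reading —
z-scoring each voxel across conditions — would instead equalize voxels; we
standardize conditions because the method's output is interpreted
feature-wise.)

For parcel set R, pair weights M, and an m × k transform T, the objective
is

    J(T) = (1/|R|²) Σ_{f1,f2} M[f1,f2] ‖ mean(β_{f1}T) − mean(β_{f2}T) ‖²
         − (1/|R|)  Σ_f Σ |cov(β_f T)|
         − S ‖T‖₁

maximized over T. Three numerical readings deserve comment:

* **The L1 term is a penalty.** Written inside an argmax with a positive
  sign it would reward large weights; its stated purpose is regularization,
  so the package subtracts it.
* **The covariance term sums the absolute values of all k × k entries** of
  each parcel's embedded sample covariance (n − 1 denominator),
  off-diagonals included. Including off-diagonals penalizes correlated
  components, which helps the k = 2 analysis produce distinct axes.
* **Scale constraint.** Both quadratic terms scale with ‖T‖², so the
  unconstrained maximizer is either 0 or unbounded. By default each column
  of T is re-projected to unit L2 norm after every gradient step, making
  the optimum well-defined and weights comparable across fits and
  bootstrap resamples. The constraint can be disabled
  (`normalize_columns=False`), in which case the huge-sparsity limit drives
  T to exactly zero and moderate settings are the user's responsibility.
* **|R| counts every class in the catalog**, including classes touched only
  by zero-weight pairs, because the normalizations divide by |R| and |R|²
  unconditionally.

The double sum over (f1, f2) visits ordered pairs, so each unordered pair
contributes twice; the two packaged masks are binary and the class pairs
they select are: same (area, division) at different eccentricity levels
(eccentricity analysis, k = 1), and different (area, division) at the same
level (area analysis, k = 2).

## Optimization

Adam (learning rate 0.01, β₁ = 0.9, β₂ = 0.999) runs for the first third
of the iteration budget (default budget 2,000) on the smooth part of the
objective, with the L1 term applied through its proximal soft-threshold
operator after every step so that small weights reach exactly zero. Adam's
sign-like steps make fast early progress but chatter near the optimum at an
amplitude set by the learning rate, so the remaining budget switches to
proximal projected-gradient ascent with a fixed step (default 0.02, halved
after ten consecutive objective decreases). Convergence is declared when
the objective's range over 50 consecutive polish iterations falls below
1 × 10⁻⁶ relative; otherwise the result is flagged non-converged. The
initialization is zero-mean Gaussian (sd 0.1, column-normalized), and every
fit takes an explicit seed, so fits are bit-reproducible.

## Bootstrap, alignment, and cross-validation

The exchangeable unit for all resampling is the acquisition **run**: a
resample draws runs with replacement, averages the raw per-run beta
matrices, re-standardizes the average, and refits from a fresh random
initialization. (Standardizing per resample, rather than resampling rows
of a once-standardized matrix, keeps every fitted matrix exactly z-scored;
with voxels as rows the two options are not interchangeable, and the run
is the unit that is actually exchangeable here.) Resamples whose fit does
not converge are excluded and counted in the result.

A fitted transform is only identified up to an orthogonal change of basis
of the embedding (and per-component sign), so the resampled transforms are
aligned by generalized Procrustes analysis: iteratively, each transform is
right-multiplied by the orthogonal k × k matrix closest to the current
consensus mean (SVD solution, reflections allowed — sign flips between
fits must be absorbed), and the consensus is recomputed, until the mean
moves < 1 × 10⁻⁹. The consensus seed is the element-wise mean, falling
back to the first transform when the mean degenerates (e.g. a set
containing T and −T). Weight and parcel-projection summaries are the
mean and sd over aligned resamples (a normal fit), with two-sided normal
CIs; the significance filter keeps features whose CI at the default 95%
level excludes zero (the level is configurable; no multiplicity
correction is applied, matching the display-rule character of the
filter).

Cross-validation splits runs by parity of their position in sorted run-id
order, fits on each half, and projects the held-out half's parcel
centroids through the fitted transform; held-out CIs come from run
bootstrap of the held-out half with the transform fixed.

## Univariate statistics

* **Summary cone contrast** of a grating pair is the mean of the two
  Euclidean norms of the per-pole (%L, %M, %S) Michelson cone contrasts.
  The packaged catalog (`data/conditions.tsv`) stores these values for all
  29 features; single-grating features store identical pole entries.
* **Percent signal change** is 100 · β_condition / β_baseline, exactly as
  printed — equality of condition and baseline gives 100, not 0. Input
  betas are assumed already divided by the baseline-gray beta, so the
  pipeline treats 100 · β as the signal change; whether 100 should be
  subtracted is an ambiguity of the printed formula that the package does
  not resolve (it affects CRF intercepts, not slopes).
* **CRF slope** is the pooled OLS slope of per-run signal change against
  cone contrast, with a run-bootstrap standard deviation.
* **Luminance bias difference** bootstraps
  Δ = (color − luminance)_ventral − (color − luminance)_dorsal over runs,
  resampling the four groups independently; the one-sided p for Δ > 0
  counts resamples with Δ < 0, ties counting half (mid-p, so a degenerate
  all-zero Δ gives p = 0.5 rather than 1).
* **Eccentricity assignment** takes the argmax ring score per voxel,
  breaking ties toward the more foveal level (an outward scan from the
  fovea); the tie-break is the first-maximum rule and is documented rather
  than configurable at the call site.

## Synthetic generator

The generator emulates a parcel-structured grating experiment with the 29
catalog features. Class mean profiles start at zero and add two planted
effects: an eccentricity gradient (±gradient · (level − 1), negative on
the 4 and 8 cycles-per-degree features, positive on the 0.2
cycles-per-degree features) and a dorsoventral offset
(±(base + slope · area rank), positive on luminance-saturation features
and negative on daylight-saturation features for dorsal parcels; reversed
for ventral; undivided areas group with dorsal). Per-run betas add a fixed
per-(voxel, condition) Gaussian effect and an independent per-run Gaussian
effect, so run resampling has genuine sampling variability and bootstrap
sds shrink roughly as 1/√voxels.

Defaults: six areas (V1–V4 divided, V3a/MT undivided), 4 levels, 20
voxels per class, 20 runs, gradient 0.5, dv base 0.1, dv slope 0.09 per
area step (the size of hierarchy growth the method is meant to detect),
noise sds 0.3 — chosen so a full fit-plus-bootstrap demonstration runs in
well under two minutes on one CPU. What the generator does **not**
emulate: spatial autocorrelation between voxels, hemodynamics and serial
correlation within runs, heavy-tailed or heteroscedastic noise, and
between-subject variability. Passing tests therefore demonstrate
correctness of the algorithms under a clean additive-Gaussian world, not
robustness to real fMRI artifacts.

## Problem sizes used in the statistical test suites

The planted-recovery and calibration suites run at deliberately small
sizes (tens of voxels per class, 6–12 runs, 50-resample bootstraps,
100–200 replicates), which keeps the whole statistical suite at around
two minutes while leaving the checked error rates well away from their
thresholds. The CI-calibration check evaluates coverage of the planted
feature's weight, with the per-replicate estimand defined as the weight
the same fit recovers from that replicate's run-noise-free voxel panel —
the correct conditional target under run resampling.

## Known limitations

* The objective is non-concave; fits find local maxima, and the bootstrap
  deliberately refits from fresh initializations so basin-hopping
  variability shows up in the CIs.
* Normal-approximation CIs from a finite bootstrap slightly undercover
  (observed ≈ 91% at nominal 95% with 50 resamples over 12 runs); the
  run-count correction factor √((n−1)/n) and sd estimation noise account
  for most of the gap.
* The voxelwise contrast map is a descriptive z-score of a weighted beta
  contrast, not a GLM statistic map: volumetric GLM refitting is out of
  scope.
* With k ≥ 2 the individual components are only meaningful up to rotation
  within the fitted subspace; downstream interpretation (e.g. the
  dorsoventral component in the area analysis) identifies a component by
  its dorsal-minus-ventral separation and orients its sign so the mean
  separation is positive.
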