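# sparseembed

Sparse supervised embedding of cortical parcel responses.

`sparseembed` addresses a question that comes up whenever a brain region can
be subdivided into labeled parcels and probed with a battery of stimuli:
**which combinations of stimulus features best distinguish the parcels?**
The motivating application is macaque retinotopic visual cortex, where
voxels carry GLM beta coefficients for 29 grating features (varying in
color axis, saturation, and spatial frequency) and belong to parcels
defined by retinotopic area, dorsal/ventral division, and eccentricity
level. Instead of the usual direction — using voxel responses to classify
stimuli — the method flips the logic and uses responses to *all* stimuli to
discover a low-dimensional functional signature that separates the
*parcels*.

## The model

Given a standardized beta matrix **β** (v voxels × m conditions), a set of
parcel labels R, and a symmetric pair-weight matrix **M** choosing which
parcel pairs matter, the method finds the m × k transform **T** maximizing

```
  (1/|R|²) Σ_{f1,f2∈R} M[f1,f2] ‖ mean(β_{f1}T) − mean(β_{f2}T) ‖²
− (1/|R|)  Σ_{f∈R} Σ |cov(β_f T)|
− S Σ |T|
```

i.e. weighted pairwise squared distances between parcel centroids in the
embedding space E, minus the summed absolute entries of each parcel's
embedded covariance, minus an L1 sparsity penalty with scale S (default
0.005). Columns of **T** are constrained to unit L2 norm, and optimization
is Adam followed by a proximal gradient polish. The pair weights implement
the two standard analyses: separate **eccentricity levels** within each
area (k = 1), or separate **areas** within each eccentricity level (k = 2).

Because any basis of E is equivalent, transforms fitted on different
bootstrap resamples are aligned by generalized Procrustes rotation
(reflections allowed) before their variance is summarized — the run-level
bootstrap then yields normal-approximation confidence intervals for every
feature weight and parcel projection, and only features whose CI excludes
zero are reported as significant.

The package also ships the univariate companion statistics (summary
Michelson cone contrast of a grating pair, percent signal change,
contrast-response-function slopes with bootstrap errors, the
dorsal/ventral luminance-bias bootstrap, max-z eccentricity assignment)
and a synthetic generator that plants an eccentricity gradient and a
dorsoventral color/luminance offset so the whole pipeline is testable
without any scanner data.

## Worked example

```bash
sse simulate --outdir demo --seed 7 --voxels-per-class 6 --runs 6
sse analyze-eccentricity --betas demo/betas.tsv --metadata demo/metadata.tsv \
    --n-boot 50 --seed 7 --outdir demo/ecc
sse analyze-areas --betas demo/betas.tsv --metadata demo/metadata.tsv \
    --n-boot 50 --seed 7 --outdir demo/area
```

prints

```
wrote 240 voxels x 29 conditions x 6 runs to demo
eccentricity analysis: converged=True, 17 significant features
area analysis: converged=True, dv slope 1.5766 (p=1.64e-09)
```

The eccentricity report (`demo/ecc/`) recovers the planted structure: all
nine spatial-frequency features are significant, and the bootstrap-mean
parcel projections along component 1 order the four eccentricity levels
monotonically (3.46, 1.12, −1.21, −3.37 from foveal to peripheral). The
area report (`demo/area/`) finds a dorsal-minus-ventral separation along
component 2 that grows along the V1→V4 hierarchy (positive regression
slope on area rank, p ≈ 2 × 10⁻⁹), matching the planted offset. The same
analyses are available as library calls
(`sparseembed.cli.run_eccentricity_analysis` / `run_area_analysis`), and
the univariate statistics via `sse univariate`.

The packaged condition catalog
(`src/sparseembed/data/conditions.tsv`) lists the per-pole L/M/S Michelson
cone contrasts of every grating feature; for example

```python
>>> import sparseembed as se
>>> cat = se.load_condition_catalog()
>>> lm = cat.get("LM_high_sat")
>>> se.cone_contrast(lm.pole_a, lm.pole_b)
11.974545097550884        # 12.0 to 3 significant figures
```

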