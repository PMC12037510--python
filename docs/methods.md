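# Methods

This note documents the statistical procedures implemented in `metcovnet`,
the synthetic cohort model used to validate them, the numerical choices
that were genuinely open, and the limits of what the validation shows.

## SUVR quantification and nuisance correction

Regional uptake is normalized per subject as
`SUVR_r = SUV_r / SUV_ref`, where `SUV_ref` is the mean over the
cerebellar reference labels. When ROI tables carry voxel counts the
reference mean is voxel-count weighted (equivalent to pooling all
reference voxels); otherwise the per-label means are averaged. ROI means
ignore non-finite voxels, since spatially normalized PET volumes commonly
pad the outside of the brain with NaN. SUVR is invariant to rescaling all
of a subject's SUVs by a positive constant, so global-intensity effects
cancel.

The age/sex correction fits, per region, an OLS model
`SUVR = b0 + b_age * age + b_sex * sex + e` (sex coded male = 1,
female = 0; the coding is configurable in the reader, since it is merely a
labelling convention for a binary covariate). Two fit scopes exist:

- **pooled** (default): one regression over both compared groups. The
  corrected value is the *fit-sample pooled mean* plus the residual. The
  mean level added back is deliberately group-independent: the corrected
  disease-minus-control contrast then equals the covariate-adjusted
  contrast. Adding each group's own mean instead would re-introduce the
  very composition difference the correction exists to remove (the
  corrected difference would become raw difference + adjusted difference);
  we verified this directly on an age-confounded null cohort, where the
  group-mean variant inflates the flagged-region count several-fold while
  the pooled-mean variant is calibrated.
- **per_group**: separate regressions in each group; the corrected value
  is the group's own mean plus the residual. Because OLS residuals are
  zero-mean within each fitted group, this preserves raw group means
  exactly — it smooths within-group age/sex variation but does not adjust
  the between-group contrast. It is retained because the source procedure
  is ambiguous about the scope.

The correction is fitted per disease-vs-control contrast, not once
globally, and uses only age and sex; BMI enters the analysis only as a
partial-correlation covariate.

Two caveats of the residual-then-t-test construction, both measurable with
the generator: (i) the pooled regression omits the group indicator, so
part of a true group effect leaks into the age slope when age and group
are correlated, attenuating the corrected contrast (about 7% at the
hypertension-like design); (ii) the subsequent t-test treats residuals as
raw observations, making it mildly conservative in proportion to the R² of
group membership on the covariates (measured mean rejection 0.04–0.047 at
nominal 0.05 for the study-like composition). Both are properties of the
mirrored procedure, not implementation artifacts.

## Screening

Per region, a two-tailed two-sample t-test compares corrected SUVRs. The
Student (pooled-variance) and Welch (Satterthwaite) variants are both
provided; by default a two-sided F test on the variance ratio at
alpha = 0.05 selects between them (the source names both tests but no
selection rule; `variance_rule="welch"`/`"student"` override). Regions are
flagged at p < alpha with no multiplicity correction by default, matching
the exploratory stance of the motivating analysis; Benjamini–Hochberg
flagging is available.

Partial correlations between a region's SUVR and a biomarker are computed
by residualizing both on the covariates (intercept + age + sex + BMI) and
correlating the residuals; the test uses `t = r sqrt(df/(1-r^2))` with
`df = n - 2 - k`. The implementation is cross-checked against the
precision-matrix formulation (agreement to 1e-10) and against an
independent library oracle in the tests. Missingness is handled
complete-case per (region, biomarker) pair — n legitimately differs across
pairs, as in the motivating study's per-panel n values — and pairs with
n < k + 3 are skipped with a warning rather than an error. Subjects
missing BMI are excluded from the partial-correlation screen but not from
the t-test screen.

## Covariance networks

A group's network has one node per analysis region and edge weights equal
to the across-subject Pearson correlation of regional SUVRs within that
group (the standard metabolic-covariance construction; with per-subject
uptake tables there is no within-subject time series, so covariance is
across subjects). Binarization keeps the top
`m = round(S * n(n-1)/2)` edges (round half-up, fixed so edge counts are
reproducible) ranked by **signed** correlation — the convention in FDG
covariance work, where "connectivity strength" means strong positive
coupling; ranking by |r| is available. Ties break by (i, j) lexicographic
order, which makes the edge sets nest monotonically in S.

The minimal fully-connected sparsity `S* = k*/(n(n-1)/2)` is found by
adding edges in ranked order into a union-find structure until one
component spans all nodes (isolated nodes therefore count as
disconnection); `S*` is bounded below by the spanning-tree sparsity 2/n.

Modularity uses Louvain optimization (networkx implementation, seeded and
single-configuration for determinism) and reports the Newman–Girvan
`Q = Σ_c (e_c/m − (d_c/2m)²)`, recomputed from the definitional formula on
the returned partition. Weighted-graph modularity and other graph metrics
(efficiency, degree comparisons) are out of scope.

## Permutation inference

The edge statistic is the raw correlation difference
`Δ_ij = r_ij(A) − r_ij(B)` (a Fisher-z mode is available). The statistic
is computed on the weighted matrices, not on binarized adjacencies: edge
presence/absence is a coarser summary, and the reported quantity of
interest is the graded connectivity change. The null re-assigns the pooled
subjects to groups of the original sizes, sampled with replacement from
the permutation space (standard at B = 5000), with p-values
`(1 + #{|Δ_perm| ≥ |Δ_obs|})/(B + 1)` — never below 1/(B+1). Exceedance
counting uses a 1e-12 tie tolerance so permutations that reproduce the
observed statistic algebraically (e.g. mirror splits) are counted as ties
regardless of floating-point rounding. The pooled subject order is
canonicalized (sorted ids) before permuting, so A-vs-B and B-vs-A with the
same seed give negated deltas and identical p-values. A zero-variance
region in a permuted split contributes Δ = 0 for its edges in that
permutation, with a warning. `compare_at_sparsity` builds both group
networks at a common S (0.35 by default; 0.55 for the small matched gout
design, whose percolation threshold is higher) and restricts reported
edges to the union of the two adjacencies; edge-wise alpha = 0.05 without
family-wise correction mirrors the exploratory design.

## Synthetic cohorts and what they validate

`generate_cohort` draws, per subject, age (group-specific normal, clipped
to 18–90 y), sex (group-specific male proportion), BMI (normal, kg/m²),
then regional SUVRs

```
SUVR_ir = base_r + effect_g,r + b_age age_i + b_sex sex_i + eps_ir
```

with `eps_i ~ MVN(0, sigma^2 C_g)`: `C_g` has unit diagonal, within-block
correlation `r_w`, between-block `r_b`, and a group-specific scale on the
off-diagonals (the shared-latent loading planting connectivity
differences); positive-definiteness is checked by Cholesky before
sampling. Defaults: base 1.2 (dimensionless SUVR), sigma = 0.1 (typical
regional SUVR residual spread), b_age = −0.002/y (gentle metabolic decline
with age), b_sex = +0.02, three residual blocks with r_w = 0.45,
r_b = 0.15 (moderate covariance structure of regional uptake). A
Student-t residual option exists for robustness checks. Planted group
effects are ±0.5 residual sd.

A biomarker linked to region r with target partial correlation rho is
generated as `alpha' covariates + lam * eps_ir + eta`, with
`lam = rho * sd(eta) / (sigma_eps sqrt(1 - rho^2))`, so the partial
correlation given the covariates is exactly rho in expectation (a closed
form, not rejection sampling). Missingness is completely at random,
matching the downstream complete-case handling, and masks values without
altering observed ones.

Presets mirror the reported designs: group sizes 497/112, 497/56, 497/11
and the 14/14 matched gout design; reported group age/sex moments; effect
direction counts 49↓+1↑ (hypertension), 38↓ (T2DM), 4↑ (obesity), 1↑
(gout); attenuated disease connectivity (scale 0.6) for
hypertension/T2DM/obesity and elevated (scale 2.0) for gout. The
`age_confounded_null` preset uses the hypertension-contrast composition
with all effects removed — and independent regions, so that Monte-Carlo
means over seeds have small standard errors. The `two_block` preset (45+45
regions, r_w = 0.8, r_b = 0.1, n = 200) exercises modularity recovery.

The generator is Gaussian, block-equicorrelated and missing-completely-
at-random. Real SUVR data have heavier tails, richer covariance geometry,
and informative missingness; passing these validations shows the
*procedures* are correct and calibrated under their own assumptions, not
that the scientific findings of any particular cohort are reproduced.

## Known limitations

- **Global sparsity thresholding under strong block structure** allocates
  edges unevenly across blocks: block-level fluctuations of the sample
  correlations tilt the global ranking, so one block can receive few edges
  and fragment. In the two-block recovery setting at S = 0.2 this caps
  exact (ARI = 1) block recovery at roughly 35–40% of seeds — isolated
  nodes carry no modularity information, so no partition optimizer can
  recover their block label. Exact recovery would require S large enough
  to cover the within-block pairs, or per-block thresholding, which is not
  part of the mirrored procedure.
- **Screen power for jointly flagging many regions**: with marginal power
  ~0.998 per planted region at the 0.5-sd/497-vs-112 design (slightly less
  after the omitted-group attenuation described above), the probability
  that *all 50* planted regions are flagged in one cohort is ~0.85–0.9,
  not ~1; single-region misses at p ≈ 0.05–0.3 are expected in ~10–15% of
  cohorts.
- Matched-control selection (greedy same-sex nearest-age within a 5-year
  caliper, seeded) is an auditable stand-in: the selection rule used for
  the original matched subsets is not documented anywhere we can mirror.
- The pipeline assumes spatially normalized inputs; image registration,
  smoothing, partial-volume correction and DICOM handling are out of
  scope, as is 3-D rendering (we only write BrainNet Viewer input files).

## Problem sizes used in the validation suite

The shipped tests and `scripts/acceptance.py` use the preset cohort sizes
throughout, with Monte-Carlo budgets chosen for a laptop-scale run:
enumeration checks at 4+4 subjects (70 assignments) vs B = 10,000;
type-I calibration at 200 simulations × B = 500 (20 regions);
correction calibration at 100 seeds; screening power at 30 seeds;
modularity recovery at 20 seeds; direction recovery at B = 1000.
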