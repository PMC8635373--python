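# Methods

## Overview

`scfc` analyzes paired structural (SC) and functional (FC) brain
connectomes on the 90-region AAL parcellation. Per subject it computes,
for the default mode (DMN), executive control (ECN) and salience (SAN)
subnetworks and the whole brain:

* **global efficiency** of the thresholded SC and FC graphs,
* **SC-FC coupling**, the Spearman correlation between log fiber counts
  and Fisher-z functional connectivity over the same region pairs.

Features are harmonized across two acquisition sites with parametric
empirical-Bayes ComBat and compared across three diagnostic groups (TDC,
ADHD inattentive type, ADHD combined type) with ANCOVA, post-hoc
contrasts, edgewise tests and brain-behavior correlations. A synthetic
cohort generator reproduces the statistical structure of such a study so
the whole pipeline is testable without access-controlled imaging data.

## Graph construction and efficiency

SC matrices are binarized at one or more fibers; the threshold defines
adjacency, so only binary (hop-count) efficiency is implemented —
weighted variants are out of scope. FC edges get two-sided p-values from
the Fisher-z normal approximation, `p = 2(1 − Φ(|z|·sqrt(t − 3)))`, with
`t` the number of time points; Benjamini–Hochberg FDR runs over all
upper-triangle edges of the matrix being thresholded (4005 for the whole
brain), and edges must additionally be positive. Global efficiency is

    E_glob = 1/(N(N−1)) · Σ_{i≠j} 1/d(i,j)

with shortest paths by breadth-first search and disconnected pairs
contributing zero (the standard convention; keeps E_glob defined on
fragmented graphs). The time-series length of the source data is not
published, so `t_points` defaults to 200; this default is arbitrary and
should be set to the real run length when known.

Raw tractography counts can be asymmetric; a region pair has a single
undirected count, so inputs are symmetrized by the elementwise mean,
rounded half-up for SC.

## SC-FC coupling

Both matrices are restricted to a subnetwork, vectorized over the strict
upper triangle, and rank-correlated (average ranks for ties). Zero-fiber
pairs have no defined logarithm and are **excluded by default**; a
`log1p` mode keeps all pairs and correlates `log(1+SC)` with FC instead.
Whether the original analysis excluded or offset zero edges is not
documented; exclusion is the primary behavior. Because Spearman is
invariant to strictly monotone transforms, using Fisher-z FC rather than
raw correlations cannot change the statistic. Couplings from fewer than
3 usable pairs are reported as missing, never as zero.

## ComBat harmonization

The location/scale model `y = α + Xβ + γ_site + δ_site·ε` is fitted by
least squares with batch indicators plus biological covariates (age, a
0/1 sex indicator, and by default group dummies, so harmonization cannot
erase group differences — `include_group_covariate=False` drops them,
since it is unknown whether diagnosis was modeled in the original).
Empirical-Bayes hyperparameters use the standard method-of-moments
estimates (normal prior for γ, inverse-gamma for δ²); posteriors are
solved by iterated conditional updates to a relative tolerance of 1e-4,
at most 100 iterations — the reference implementation's defaults. All
features are harmonized in a single fit: pooling information across
features is the point of the EB step. The implementation matches
Bioconductor `sva::ComBat` to ~1e-6 on shared inputs (tested).

Note a structural property of the model, not a defect: with zero batch
effect the per-batch scale estimate (ddof = 1) differs from the pooled
variance (ddof = 0) by an O(1/n) factor, so "harmonizing" identical
batches reproduces the input only up to that factor. Likewise EB
shrinkage removes the *systematic* site effect while deliberately
retaining per-feature noise in the site contrast, so shift-recovery is
assessed on the feature-averaged site gap.

## Statistics

* **Group test** — partial F for the group factor: full model
  (intercept, group dummies, age, sex) vs reduced (intercept, age, sex);
  raw group means ± SEM are reported alongside. Age is used uncentered
  (centering does not change the partial F); sex is one indicator.
* **Post-hoc** — Tukey–Kramer on covariate-adjusted residuals for the
  table-style adjusted p-values (the original's adjustment method is
  unnamed; this is a documented assumption), plus unadjusted Welch t and
  Bonferroni variants for figure-style contrasts.
* **Edgewise contrasts** — Welch t per upper-triangle edge on
  `log(1+SC)` or Fisher-z FC, BH FDR across the tested edge set;
  zero-variance edges are excluded and counted.
* **Behavior** — Pearson correlations (Spearman via flag) of DMN
  coupling with hyperactivity and inattention per group, plus the
  independent-samples Fisher r-to-z test
  `z = (atanh r₁ − atanh r₂)/sqrt(1/(n₁−3) + 1/(n₂−3))` between groups.
  This test form was chosen because it exactly reproduces the published
  worked example (r = 0.25, n = 75 vs r = 0.62, n = 70 → p ≈ 0.0057).
  Outlier sensitivity re-runs take an explicit exclusion list rather
  than an automatic detector, since no published criterion exists.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions, not tuning knobs.

* **SC**: Erdős–Rényi edge pattern at a group-specific density (TDC
  0.30, ADHD-I 0.25, ADHD-C 0.22 — lower structural density in ADHD,
  lowest in the combined type) with counts `round(exp(N(4.0, 1.2²)))`,
  clipped below at 1 on sampled edges.
* **FC**: `t_points` i.i.d. multivariate-normal vectors with target
  covariance `(1−α)I + αC`, where `C` is the standardized `log(1+SC)`
  matrix projected to the nearest positive-definite correlation matrix
  (eigenvalue clipping at 1e-8, re-standardized diagonal); the returned
  matrix is the Fisher-z of the sample correlation. Generating FC from
  finite-length series (rather than adding noise to SC) makes FC a
  genuine correlation matrix and gives the FDR thresholding stage its
  degrees of freedom. Mixing weight α ∈ [0,1] makes measured coupling
  monotone in α.
* **α defaults** (TDC 0.43, ADHD-I 0.36, ADHD-C 0.53) were fixed once
  from a Monte-Carlo sweep of the α → mean-measured-DMN-coupling curve
  so that group mean couplings land near the published pattern
  (≈0.31/0.27/0.37); they are calibration goals, not guarantees.
* **Behavior**: hyperactivity = group mean + `beta_hyper`·standardized
  measured DMN coupling + noise (total SD ≈ `swan_sd`); inattention is
  constructed to correlate with hyperactivity at `rho_inatt_hyper`.
  Group means (−0.9/0.2/1.2 hyperactivity, −0.8/1.2/1.4 inattention for
  TDC/ADHD-I/ADHD-C), male fractions (0.36/0.72/0.80) and the subtype
  inattention-hyperactivity correlations (0.25 inattentive, 0.62
  combined) follow the published cohort table; the TDC correlation is
  not published and is set to 0.30. `beta_hyper` defaults to −0.3 for
  ADHD-I and 0 elsewhere, mirroring the reported negative
  coupling-hyperactivity association in the inattentive subtype.
* **Sites**: Bernoulli(0.5) assignment independent of group
  (configurable to induce confounding); site effects are applied to the
  *feature table* as `scale·x + shift` (default shift 0.05 on site 2),
  emulating site-dependent measurement offsets.
* **Demographics**: ages uniform on 6–17 years; group sizes default to
  56/75/70 (201 subjects).

What the generator does **not** emulate: spatially structured anatomy
(distance-dependent connectivity, hubs, modules), baseline functional
correlations on structurally unconnected edges (synthetic FC
efficiencies therefore run lower than empirical ones), hemodynamics,
head motion, or site effects in the raw matrices themselves. Passing
tests therefore show the *analysis machinery* is correct and calibrated,
not that the scientific findings would replicate on real data.

## Numerical choices and degenerate inputs

* BH, Spearman, Welch t, Tukey and the partial F go through
  scipy/statsmodels; each has an independent brute-force oracle in the
  test suite (step-up rule, rank-then-Pearson, normal equations,
  Floyd–Warshall for BFS distances).
* Matrices must be finite; asymmetry beyond 1e-10 triggers
  symmetrization; diagonals are forced to zero (Fisher-z of the unit
  diagonal is infinite and carries no information).
* `t_points ≤ 3` is rejected (undefined standard error); batches with a
  single subject and covariates confounded with batch are rejected with
  the offending column named.
* Constant features give F = 0; zero-variance correlation inputs raise;
  sample correlations are clipped at |r| ≤ 1 − 1e-6 before `atanh`.

## Problem sizes used in validation

The replicated end-to-end check runs 50 seeded 201-subject cohorts at
the default 90 nodes and 200 time points; error-calibration suites use
2000 null ANCOVA replicates (30/group) and 500 edgewise replicates (100
edges); harmonization recovery uses 50 subjects per site and 40
features. These sizes give the Monte-Carlo bands stated in the tests
while keeping the full suite in the minutes range on a laptop core.

## Known limitations

* Only binary global efficiency; no weighted metrics, clustering or
  modularity.
* Parametric ComBat only; no ComBat-GAM or longitudinal variants, and no
  harmonization of raw matrices.
* The AAL region-name mapping for the subnetworks follows standard
  AAL-90 naming; exact atlas indices are user-overridable via a JSON
  definition file.
* Edgewise FC "node" summaries and regional coupling variants are not
  implemented.
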