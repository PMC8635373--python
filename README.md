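# scfc — structure–function connectome coupling analysis

`scfc` is a Python package for asking how closely a brain's functional
organization follows its anatomical wiring, and whether that adherence
differs between diagnostic groups. It takes per-subject **structural
connectivity** (SC: fiber counts between 90 AAL regions from
tractography) and **functional connectivity** (FC: Fisher-z correlations
between regional resting-state time series) and computes, per subject
and per subnetwork (default mode, executive control, salience, whole
brain):

* **global efficiency** of the thresholded network,
  `E_glob = 1/(N(N−1)) Σ_{i≠j} 1/d(i,j)`, with SC binarized at ≥1 fiber
  and FC thresholded at positive, FDR-significant edges;
* **SC-FC coupling**, the Spearman correlation ρ between log fiber
  counts and FC over the same region pairs.

Downstream it removes acquisition-site effects with parametric
empirical-Bayes **ComBat** (implemented in-package, numerically matched
against Bioconductor `sva`), then runs the inferential layer: ANCOVA
(partial F for group with age/sex covariates), Tukey–Kramer/Welch
post-hoc contrasts, edgewise Welch-t maps with Benjamini–Hochberg FDR,
per-group brain–behavior Pearson correlations, and the Fisher r-to-z
test for a difference between two independent correlations,
`z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`.

Because the motivating cohort (a two-site pediatric ADHD sample) is
access-controlled, the package ships a first-class **synthetic cohort
generator** that emulates the study's statistical structure — group
sizes, demographics, group-dependent structural density, tunable SC→FC
coupling strength, two-site feature shifts, and behavior scores with
group-specific links to DMN coupling — so every stage is testable end to
end. It is aimed at network-neuroscience researchers who want a tested,
reproducible reference implementation of this analysis style.

## Worked example

```python
from scfc import CohortConfig, independent_corr_diff_test
from scfc.pipeline import analyze_cohort

# difference between two subtype correlations (r, n printed per group)
res = independent_corr_diff_test(0.25, 75, 0.62, 70)
print(f"z = {res.z:.3f}, p = {res.p:.4f}")

# full pipeline on a default synthetic cohort (201 subjects, 90 nodes)
out = analyze_cohort(CohortConfig(seed=1))
report = out["group_report"]
print(report.loc["Eglob_SC__DMN", ["F", "p"]])
coupling = out["features"].loc["coupling__DMN"]
print(coupling.groupby(out["manifest"]["group"]).mean().round(3))
```

prints

```
z = -2.766, p = 0.0057
F    1.961801e+01
p    1.712849e-08
Name: Eglob_SC__DMN, dtype: float64
group
ADHD-C    0.448
ADHD-I    0.300
TDC       0.325
Name: coupling__DMN, dtype: float64
```

i.e. the two correlations differ significantly (p ≈ 0.0057); on the
synthetic cohort the structural efficiency of the DMN separates the
groups (partial F = 19.6), and mean DMN coupling is highest in the
combined subtype — the effect pattern the generator is calibrated to.

## Command line

```bash
scfc simulate  --config cfg.yaml          # cohort -> manifest + matrices
scfc validate  out/manifest.csv           # input checks, non-zero exit on findings
scfc features  --config cfg.yaml          # efficiencies + couplings CSV
scfc harmonize --config cfg.yaml          # ComBat across sites
scfc stats     --config cfg.yaml          # group/edgewise/behavior reports
scfc run-all   --config cfg.yaml --seed 1 # everything, with a run log
```

Matrices travel as tab-delimited text with a JSON node-label sidecar;
all reports are CSV. See `docs/methods.md` for the model details,
generator assumptions and numerical choices.

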