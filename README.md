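# nmrmet

A tested, reusable pipeline for two-group 1D ¹H NMR metabolomics of tissue
extracts — the workflow used to profile heart, kidney and skeletal-muscle
metabolomes of mice on standard-chow (SC) versus high-fat (HF) diets:
spectral preprocessing, PLS-DA with multi-layer validation, normality-gated
univariate statistics with standardized effect sizes and FDR control, and
quantitative lipid-saturation / methylamine profiling. A first-class
synthetic-cohort simulator with known ground truth makes every stage
testable without access to the original spectra.

## Who it is for

Metabolomics analysts who have processed, real-valued 1D ¹H spectra
(ppm axis + intensities; two-column text or JCAMP-DX-style files) of
aqueous or lipophilic tissue extracts, per-sample metadata (tissue, diet
group, wet weight), and want the full discriminant-analysis and
quantification stack as reproducible, scriptable Python instead of a chain
of GUI tools.

## What it computes

**Preprocessing** (`nmrmet.preprocess`) — chemical-shift referencing (TSP
δ 0.0 aqueous / pyrazine δ 8.6 lipophilic), solvent-region exclusion
(water δ 4.70–5.00, methanol δ 3.34–3.37, chloroform δ 7.03–7.49, pyrazine
δ 8.50–8.80), recursive segment-wise peak alignment (RSPA), total-area
normalization, and column scaling (mean-centering, Pareto, or
unit-variance). The stage order is enforced.

**Chemometrics** (`nmrmet.chemometrics`, `nmrmet.validation`) — PCA and
PLS-DA as model objects whose `fit()` returns a results object. PLS-DA is
NIPALS PLS1 against the 0/1 class vector with per-component deflation of X;
variable importance to projection is

    VIP_j = sqrt( p · Σ_a SSY_a (w_aj/||w_a||)² / Σ_a SSY_a ),
    SSY_a = q_a² t_aᵀt_a,

so mean(VIP²) = 1. Validation layers: stratified 7-fold Q² = 1 − PRESS/TSS;
a 500-permutation test with p = (1 + #{Q²_perm ≥ Q²_obs})/(1 + n_perm);
Monte-Carlo cross-validation (stratified 1/7 withheld per iteration,
500 iterations) reporting the Q² distribution, classification rate,
sensitivity and specificity with a label-permuted parallel run; and
stratified 5-fold AUROC of a random-forest classifier with per-fold
permutation null bands.

**Univariate statistics** (`nmrmet.univariate`) — per-signal window
integration on the normalized (unscaled) matrix; Shapiro–Wilk-gated Welch
t-test / Mann–Whitney; standardized mean difference ES = (mean_HF −
mean_SC)/s_pooled with its 95% CI half-width

    ES_err = 1.96 · sqrt( (n₁+n₂)/(n₁n₂) + ES²/(2(n₁+n₂)) );

Benjamini–Hochberg FDR within each tissue × phase family; fold-change
heatmap tables with `*`/`#` significance marks.

**Quantification** (`nmrmet.lipids`) — fatty-acid chain classes from
proton-stoichiometric integrals (CH₃/3 for total chains, allylic/4 for
unsaturated, bis-allylic/2 for polyunsaturated, ω-3 CH₃/3), reported as
%SFA/%MUFA/%PUFA/%ω-3 and total FA in µmol per g wet tissue against the
0.24 mM pyrazine reference; TMA/DMA/TMAO in µmol/g against 0.1 mM TSP, with
TMAO recovered from under the taurine/glucose overlap by subtracting their
contributions estimated from resolved resonances (taurine δ 3.42, anomeric
glucose δ 5.23).

**Simulator** (`nmrmet.simulate`, `nmrmet.signals`) — Lorentzian-multiplet
spectra over a 14 ppm window at 500.13 MHz with configurable linewidth,
peak jitter, baseline noise and internal references; log-normal
within-group concentrations with exact injection of target standardized
mean differences; full ground-truth recording for parameter-recovery tests.

## Worked example

```python
import nmrmet as nm
from nmrmet.univariate import analyze_windows, default_windows, integrate_windows

design = nm.CohortDesign(phase="aqueous", n_SC=12, n_HF=11, n_points=8192, seed=7)
spectra, truth = nm.simulate_cohort(design, nm.build_default_library("aqueous"), seed=7)

refd = [nm.reference_axis(s) for s in spectra]
m = nm.build_matrix(refd, axis=design.axis)
m = nm.exclude_regions(m, nm.default_exclusions("aqueous"))
m = nm.normalize_total_area(nm.align_rspa(m))

res = analyze_windows(integrate_windows(m, default_windows("aqueous")), m.groups)
print(res[["ES", "ES_err", "p_raw", "p_fdr", "test_used"]].round(3))

scaled = nm.scale_columns(m, "uv")
report = nm.validate(scaled.data.to_numpy(), y=scaled.y, A=2,
                     n_perm=100, mccv_iter=200, auroc_perms=5,
                     rf_estimators=100, seed=7)
print(report.summary())
```

prints (abridged):

```
                          ES  ES_err  p_raw  p_fdr     test_used
alanine               -1.218   0.891  0.008  0.022       welch_t
pyruvate               1.276   0.897  0.006  0.020       welch_t
trimethylamine        -1.466   0.921  0.004  0.020  mann_whitney
glycerophosphocholine  1.554   0.933  0.005  0.020  mann_whitney
uracil                 1.704   0.955  0.001  0.011       welch_t
...
PLS-DA validation (A=2, seed=7)
  R2X=0.149  R2Y=0.988  Q2=0.382
  permutation p=0.009901 (100 permutations)
  MCCV: Q2_median=0.366 CR=0.814 sens=0.713 spec=0.915
  AUROC=0.933 (95% CI 0.838-1.029)
```

Reading the numbers: the simulated HF kidney cohort shows the injected
pattern — decreased trimethylamine and alanine, increased pyruvate, GPC and
uracil — each with its standardized effect size, the CI half-width printed
as its error, and FDR-adjusted p-values. The PLS-DA separates the groups
with modest cross-validated predictive power (Q² ≈ 0.4, typical for an
11-12 animals/group aqueous profile), a permutation p at the floor of 100
permutations, and an AUROC near 0.93.

The same workflow runs from the shell:

```
nmrmet run --seed 7 --out results_run      # all tissue × phase analyses
nmrmet report results_run/manifest.json    # tables + validation summaries
```

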