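# Methods

## The measurement model

A processed 1D ¹H spectrum is modelled as a sum of area-normalised
Lorentzian multiplets on a 14 ppm axis (−0.5…13.5 ppm, the span of a
7002.801 Hz sweep at 500.13 MHz):

    I(δ) = Σ_signals c · n_H · Σ_lines f_l · L(δ − (δ₀ + Δ_jitter + o_l); γ) + ε(δ)

with c the metabolite concentration (mM-equivalents in the tube), n_H the
proton count of the resonance, f_l binomial line fractions (d 1:1, t 1:2:1,
q 1:3:3:1; higher multiplets rendered as one unresolved line of doubled
width), o_l the line offsets at J = 7.3 Hz (0.0146 ppm), and L a unit-area
Lorentzian. Because L integrates to 1, the integral of a resonance equals
c·n_H exactly, which is what makes closed-loop recovery tests meaningful.

Key simulator parameters, defaults, and why:

| parameter | default | rationale |
|---|---|---|
| axis | 16,384 points over −0.5…13.5 ppm | resolves a 0.002 ppm line (≥2 points/half-width) at a fraction of acquisition-grade sizes; configurable |
| linewidth γ | 0.002 ppm (≈1 Hz) | typical for well-shimmed extracts with mild line broadening |
| 'm' broadening | 2 × γ | unresolved multiplets are wider than resolved lines |
| jitter SD | 0.003 ppm per sample | pH/matrix-driven shift variability, the disturbance RSPA exists to fix |
| noise SD | 2·10⁻⁵ of the tallest clean signal | see "dynamic range" below |
| within-group CV | 25 % (log-normal) | typical biological variation; an assumption, not a measured value |
| group sizes | 12 SC / 11 HF (10 HF for heart) | the study design being emulated |
| references | TSP 0.1 mM (9H, δ 0.0) aqueous; pyrazine 0.24 mM (4H, δ 8.6) lipophilic | the stated reference compounds and levels |
| tissue weight | 0.15 g in 600 µL | a realistic wet-tissue aliquot |

**Noise and dynamic range.** Noise is parameterized as a fraction of the
tallest clean signal. In lipophilic extracts the (CH₂)ₙ envelope is ~250×
taller than the 0.24 mM pyrazine reference, so the reference's own SNR —
not the nominal noise fraction — limits absolute quantification: a 2%
recovery tolerance requires reference-integral precision near 1%, i.e.
reference SNR of a few hundred. The default noise fraction (2·10⁻⁵,
reference SNR ≈ 400) models the high-SNR, fully relaxed acquisitions used
for quantification. At noise fractions above ~10⁻⁴ of the tallest lipid
peak, no estimator can quantify the reference to a few percent; this is a
property of the dynamic range, not of the implementation.

**Effect-size injection.** Within-group concentrations are log-normal with
SD proportional to the mean (CV fixed). The HF mean is scaled by the exact
solution r of r − 1 = d·CV·√((1+r²)/2) (d the target standardized
difference), so the *population* pooled-SD standardized difference equals
the target without first-order approximation. Sampling variability of the
*estimated* effect size then follows the usual SE(d) =
√((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))) — the same formula whose 1.96-multiple is
reported as the "ES error" — and the simulator recovery tests assert
coverage of that band rather than ad-hoc tolerances.

**Stoichiometric consistency (lipophilic cohorts).** Fatty-acyl signals
share chains, so drawing them independently can produce impossible samples
(more unsaturated than total chains). The cohort generator therefore draws
latent chain classes (SFA, MUFA, PUFA; ω-3 a fixed fraction of PUFA) and
derives every fatty-acyl signal from them via the proton stoichiometry; the
MUFA and PUFA latents carry the injected group effects (−0.98 and +2.64
standardized), so the linoleic and bis-allylic windows inherit the PUFA
effect. Non-acyl lipids (cholesterol, PC/LPC, glycerides) are independent.
One consequence: the olefinic "UFA" marker's group difference is emergent
(MUFA + 2·PUFA), not separately injected.

## Preprocessing

Stage order is fixed and enforced: reference → exclude → align → normalize
→ scale. Referencing moves the maximum-intensity point in the search window
(TSP −0.2…0.2; pyrazine 8.4…8.8 ppm) exactly onto the nominal shift; a
sample with no peak 5× above the robust (MAD) noise floor is flagged, not
silently shifted. Exclusion drops every column whose center lies inside a
closed interval; the defaults are the four solvent/reference regions listed
in the README. Normalization divides each row by its total over *retained*
columns. Scaling offers mean-centering, Pareto (÷√SD) and unit variance
(÷SD); zero-variance columns are dropped with a log entry rather than kept
as zeros, and pre-scaling column SDs are retained so loading weights can be
back-scaled for display.

**RSPA.** The alignment contract: the reference is the sample with the
highest mean Pearson correlation to all others; each other sample is
shifted as a whole, then recursively segmented at reference-intensity
minima (middle half of each segment), each segment shifted by the
cross-correlation-maximizing lag within ±max_shift (default 0.02 ppm),
recursion stopping below min_seg_points (default 64) or at segment
correlation ≥ 0.98. Edges are filled with boundary values. Ties prefer zero
lag, a segment shift is kept only if it strictly improves its correlation,
and a whole sample is kept only if its overall correlation to the reference
does not decrease — so the mean correlation is non-decreasing by
construction, and per-sample area is conserved to well within 0.5% because
split points sit at intensity minima.

## Chemometrics

PLS-DA is NIPALS PLS1 against the 0/1 class coding (SC=0, HF=1), X and y
mean-centered internally with training means (so resampling refits are
correct on subsets), X deflated per component; prediction thresholds the
linear predictor at 0.5. Defaults: A = 2 components (two-dimensional score
plots and LV1 loading profiles are the standard display; an auto-rule "add
a component while ΔQ² > 0.01" is available via `cv_q2`'s per-component
output). Q² uses stratified 7-fold CV with TSS about the overall class
mean; the permutation p uses the +1 small-sample correction so p = 0 is
unattainable. MCCV interprets "seven blocks" as withholding a stratified
1/7 of samples per Monte-Carlo iteration (the construction is otherwise
unspecified); degenerate splits are resampled and logged. The AUROC layer
uses a random forest (500 trees, default depth, seeded) with stratified
k-fold (k = 5, clamped to the smaller class when needed) and per-fold
label-permutation nulls; its 95% CI is mean ± 1.96·SD/√k across folds. All
resampling is seeded and the seed is recorded in the report.

**UV scaling and VIP ranking.** Unit-variance scaling amplifies every
baseline-noise column to unit variance; on a full-resolution matrix with
thousands of signal-free columns, the maximum of thousands of random
class correlations competes with genuine effects, so VIP ranking for
recovery checks is computed on the window-integral matrix (targeted
profiling) where every variable is a real signal. This is a property of UV
scaling, not an implementation artifact; Pareto scaling on full resolution
does not suffer from it because weights retain a √SD magnitude factor.

## Univariate statistics

Integration windows are centered on the library's reporting signal with
multiplicity-dependent half-widths (singlets ±0.02, doublets/triplets
±0.03 plus the multiplet span, unresolved multiplets ±0.04), narrowed in
crowded regions (pyruvate 2.37/succinate 2.40; the 2.00/2.04 allylic pair)
— window bounds are configuration, not science, and are fully overridable.
The TMAO/taurine/glucose cluster near δ 3.26 is deliberately absent from
the window set; it is handled by the overlap-subtracting estimator.

The normality gate is Shapiro–Wilk at α = 0.05 in *both* groups (the
conventional reading); Welch's t when both pass, two-sided Mann–Whitney
otherwise (exact for n ≤ 8, normal approximation with tie correction
above). Effect sizes are pooled-SD standardized mean differences oriented
HF − SC, with the 95% CI half-width 1.96·√((n₁+n₂)/(n₁n₂) + ES²/(2(n₁+n₂)))
reported as the error. FDR is Benjamini–Hochberg with the family defined as
all windows of one tissue × phase table (an assumption; the original family
definition is unknown). Constant data yield an undefined p, reported as
such.

## Quantification

All integrals used quantitatively are corrected by the analytic fraction of
a Lorentzian multiplet of the configured half-width falling inside the
finite window (finite windows clip 1–6% of Lorentzian tails). The total-FA
estimate additionally subtracts the (CH₂)ₙ tail leaking into the CH₃
window, with the methylene level estimated from its own window — the
"corrected CH₃ signal". The pyrazine integration window (8.55–8.65 ppm) is
narrower than its search band because integral noise grows with window
width while signal coverage saturates.

Chain-class arithmetic: chains = I(CH₃ 0.80–1.05)/3; ω-3 = I(0.93–1.00)/3;
PUFA = I(bis-allylic 2.70–2.88)/2; UFA = I(allylic 1.94–2.10)/4;
MUFA = UFA − PUFA; SFA% = 100 − UFA%. Pathologies are clipped with a
warning, preserving closure: MUFA < 0 (overlap), SFA < 0 (all-UFA samples
with tail leakage, unsaturated classes renormalized). Bis-allylic protons
are counted as 2 per PUFA chain (linoleic-like); highly unsaturated chains
(DHA) are under-counted — a known limitation. Quantification refuses
spectra not flagged fully relaxed (long-d1 acquisitions) unless overridden.

TMAO estimation subtracts, from the δ 3.22–3.30 window, the taurine
contribution predicted from its resolved δ 3.42 triplet (equal proton
count) and the glucose contribution predicted from the anomeric δ 5.23
doublet scaled by the in-window/anomeric proton ratio (default 1.0, one
ring proton in the window per anomeric proton), floors the remainder at
zero, and flags the sample if the pre-floor value is below −3× the window's
noise. Concentrations convert to µmol per g wet tissue via
c(mM) × 0.6 mL / weight(g).

## What the simulator does and does not establish

Passing recovery tests shows the estimators are unbiased and correctly
calibrated *under the generative model*: Lorentzian lines at catalogued
positions, log-normal biology, white noise, flat baseline, no metabolite
correlations or pH-dependent shift drifts beyond random jitter, no
satellite peaks or relaxation/NOE attenuation. Real spectra violate all of
these to some degree — most importantly baseline roll, unmodelled overlaps,
and T₁/NOE weighting on non-relaxed acquisitions — so recovery tolerances
here are lower bounds on real-data error, not guarantees. The headline
multivariate statistics of any particular animal study (Q², permutation p,
AUROC) depend on that cohort's spectra and are *not* reproduced by
simulation; the validation machinery, not the values, is what this package
warrants. Problem sizes used in the automated checks (8,192–16,384 axis
points, 50-seed recovery batches, 99–500 permutations) are the package's
own choices for routine verification; every knob scales up by
configuration.

## Numerical choices and degenerate inputs

- PCA via SVD with deterministic sign (largest-magnitude loading element
  positive); components beyond the matrix rank are refused.
- NIPALS stops on weight convergence (1e-12) or rank exhaustion; an exactly
  zero score vector is an error, not a NaN.
- Cross-correlation lag ties prefer zero displacement; alignment never
  shifts when shifting does not strictly help.
- Exclusion intervals are closed; a column is dropped when its center lies
  inside. Overlapping intervals are merged on construction.
- Permutation p-values use the +1 correction; with n_perm = 1 the only
  attainable values are 1/2 and 1.
- Two-column/JCAMP parsing reports the offending line number; axes are
  re-sorted to descending ppm and duplicate ppm values are an error.
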