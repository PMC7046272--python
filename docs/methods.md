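# Methods

This note records the models implemented in `tdvpipe`, the parameter
choices that matter, what the synthetic data does and does not emulate,
and the numerical decisions that make results bit-stable.

## Diffusion models

**ADC mapping.** The apparent diffusion coefficient is fitted per voxel
by ordinary least squares of `ln S` against b (`S(b) = S0·exp(−b·ADC)`).
The log-linear form is deterministic and reduces exactly to the
two-point closed form `ADC = ln(S(b₀)/S(b₁))/(b₁−b₀)` for the clinical
b = {0, 1000} s/mm² whole-body acquisition. Voxels with any non-positive
signal are flagged invalid and excluded from every downstream mask (they
render as 0 in computed DWI). Negative fitted slopes — possible under
noise when signal rises with b — are clamped to ADC = 0 so the map is
non-negative wherever defined. All diffusion coefficients are stored in
mm²/s; config files accept the conventional display unit ×10⁻³ mm²/s
and convert once at parse time, which avoids the classic 10³ unit bug.

**Computed DWI.** A volume at an arbitrary (typically unacquired)
b-value is synthesized voxelwise as `S0_fit·exp(−b_target·ADC_fit)`.
With a noiseless monoexponential source and b_target = 999 from a
b = {0, 1000} acquisition, the output matches the acquired b = 1000
volume to well under 0.5%.

**IVIM.** ROI-mean signal is fitted with
`S(b)/S(0) = f·exp(−b·D*) + (1−f)·exp(−b·D)`. A simultaneous
3-parameter fit of 9 noisy points is poorly identifiable, so the
package uses the standard segmented strategy: (1) fit D log-linearly on
b ≥ 200 s/mm², where the perfusion compartment has essentially decayed;
(2) fix D and fit (f, D*) by bounded nonlinear least squares
(f ∈ [0, 1], D* ∈ [D, 0.5 mm²/s], init f = 0.1, D* = 10·D, tolerances
1e-10, ≤ 500 evaluations). Because a small perfusion residual above
b = 200 biases step 1 (for marrow-like D ≈ 0.35×10⁻³ the D* estimate
came out ~1% high), the two steps are then alternated three times,
subtracting the current perfusion component from the high-b tail before
refitting D. On noiseless data this converges to the simultaneous
least-squares solution (verified against a full 3-parameter fit used as
a test oracle only); on Rician-noisy data at SNR 50 the mean fitted f
over 200 replicates stays within ±0.01 of the generating f = 0.247.
Non-convergence returns the best iterate with `converged=False`, never
an exception.

## Tumour-burden segmentation

The chain is: computed DWI (b = 999) → min–max normalization to 0–255 →
background threshold (> 97) → Otsu binarization of the in-mask
intensities → exclusion-mask subtraction → ADC band → tDV + histogram
features. Design choices:

* **Intensity normalization.** The published background threshold (97)
  only has meaning on a fixed intensity scale, which scanners do not
  share; min–max rescaling to 0–255 makes it portable, and both the
  scale and the threshold are config keys.
* **Otsu.** Candidate levels are the interior edges of a 256-bin uniform
  grid over the data range; the returned level maximizes the
  between-class variance `w₀w₁(μ₀−μ₁)²` with class moments computed
  from the data values themselves (not bin centres), so the operation is
  exactly reproducible by exhaustive search. Ties break toward the lower
  level. Note that for two well-separated clusters the objective is
  nearly flat across the gap and its argmax sits just above the lower
  cluster — the same behaviour as `skimage.filters.threshold_otsu` —
  which still partitions the clusters correctly. Constant input has no
  threshold and errors. Otsu is applied to the 3D volume by default;
  applying it to the 2D MIP instead is a config flag
  (`otsu_on_mip`), since published descriptions of such workflows are
  ambiguous between the two.
* **ADC band.** Strict lower bound, inclusive upper bound
  (`adc_lower < ADC ≤ adc_upper`), defaults 0.55×10⁻³ and 2.0×10⁻³
  mm²/s, following the usual inequality conventions for these cuts; the
  sweep utility compares lower cuts {0.45, 0.55, 0.65}×10⁻³.
* **Exclusions.** The manual removal of non-skeletal bright structures
  is replaced by a user- or ground-truth-supplied mask; no automatic
  skeleton detection is attempted.
* **Histogram features.** Percentiles use linear interpolation between
  order statistics; skewness and kurtosis are moment-based
  (population form), with kurtosis reported as Fisher excess
  (normal = 0) and stated as such in output metadata. Fewer than 4
  voxels, or data whose relative standard deviation is below float
  precision, yield flagged (NaN) shape moments.
* tDV counts every disease voxel (extramedullary disease is not
  distinguished from bone disease).

## Fat fraction

`FF = 100·fat/(fat+water)` per voxel — the standard Dixon fat-signal
fraction; voxels with zero denominator are flagged NaN. ROI statistics
are the mean of per-voxel FF (mean-of-ratios); the ratio-of-ROI-mean-
signals alternative can be computed by taking ROI means of the raw pair,
but mean-of-ratios is the implemented default and recorded in the map's
`method` field. ROIs are declared in a small table (plane, slice,
corner, extent) rather than drawn interactively, mirroring manual
placement over L1–L3; areas are validated against protocol bounds
(282–525 mm² for Dixon, 245–480 mm² for DWI ROIs) with a warning, not a
failure. Water–fat separation itself (multi-echo reconstruction,
spectral modelling, T2* correction) is out of scope: vendor-style
water/fat images are the input contract.

## Response statistics

* **Percentage change** is `100·(follow-up − baseline)/baseline`; zero
  baselines are excluded with a logged count.
* **Wilcoxon signed-rank** drops zero differences, ranks |d| with
  midranks, and computes the exact two-sided p for n ≤ 25 by subset-sum
  dynamic programming over all 2ⁿ sign assignments (doubling ranks keeps
  midranks integral, so the enumeration is exact with ties); larger
  samples use the normal approximation with tie correction.
* **ROC.** AUC is the Mann–Whitney concordance estimator with half
  credit for ties; SE by Hanley–McNeil by default (DeLong behind a
  flag), CI = AUC ± 1.96·SE reported untruncated with a clipped variant
  alongside, since symmetric normal intervals near AUC = 1 exceed 1.
  Cutoffs maximize Youden's J over midpoints between consecutive
  distinct scores; ties in J break toward higher specificity. A
  per-variable direction convention (lower-is-positive for tumour-burden
  markers such as tDV, M protein, β₂-microglobulin; higher-is-positive
  for FF, mean ADC, haemoglobin) is applied by exact or prefix match on
  the variable name.
* **Logistic model.** Implemented as a binomial GLM with logit link
  (fitted by IRLS via statsmodels) — reports of this kind sometimes
  label it a "general linear model", but odds ratios imply the logit
  link. Wald SEs and p-values; OR = exp(β) with CI exp(β ± 1.96·SE).
  Complete or quasi-complete separation is detected (fitted
  probabilities at the boundary or exploding SEs) and flagged on the
  result rather than raised or hidden. Variables enter the
  multivariable model when their univariate logistic p < 0.05.
* **Kappa.** Linear weights `1 − |i−j|/(k−1)`.
* **No multiple-testing correction** is applied anywhere; report
  metadata says so.

## Synthetic data

The phantom generator emulates the *geometry and contrast logic* of a
whole-body study at desk scale — default grid 64×64×128 at 2 mm
isotropic (≈ 4.2 L field of view), a skeletal marrow compartment
(spine column, pelvis slab, two femora, ~240 ml capacity), spherical
focal lesions rasterized centre-in-voxel, diffuse involvement as a
contiguous run of marrow voxels sized exactly to a target volume, one
high-ADC organ (ADC 2.5×10⁻³ mm²/s, above the shine-through cut) and
one non-skeletal bright structure whose ADC lies *inside* the disease
band so that only the exclusion mask can remove it — exercising the two
filters independently. DWI signal follows the IVIM equation exactly
(perfusion only in uninvolved marrow, f = 0 in lesions and organs);
Dixon pairs satisfy `fat/(fat+water) = FF/100` per tissue; noise is
Rician (`sqrt((m+g₁)² + g₂²)`), deterministic given a seed. Signal
scale is arbitrary with lesion s0 = 1000 by default and noise expressed
on that scale. Normal marrow defaults: ADC 0.35×10⁻³ mm²/s (chosen to
sit below the disease band, a value not pinned by published thresholds),
FF 40%, s0 = 300 — dim enough at computed b = 999 for Otsu to separate
marrow from disease, bright enough to survive the background threshold.

What it does **not** emulate: acquisition physics (coils, EPI
distortion, fat suppression), multi-station acquisition and inter-station
intensity steps (a single concatenated volume stands in for the 4-station
scan), partial-volume effects, anatomical realism of lesion shapes, or
biological heterogeneity within tissues. Passing phantom tests therefore
validates the *computational chain* — that each stage implements its
stated rule exactly and composes correctly — not clinical segmentation
accuracy on real scans.

The cohort generator draws per-variable percentage changes from
Gaussian group distributions (defaults: responder/non-responder means ±
SDs such as ΔFF 94.3 ± 45.5 vs 24.7 ± 34.1, ΔtDV −54.6 ± 32.1 vs
45.7 ± 45.5, with group sizes 15/35), plus baselines from group-specific
Gaussians truncated to be positive by rejection sampling (percentage
change needs positive denominators, and e.g. a FF baseline distribution
of 32.2 ± 24.7 has non-trivial negative mass). Variables are drawn
independently within patients; real serological and imaging indices are
correlated, so simulated multivariable models are optimistic about
independence and are used only for direction/recovery checks. Under the
default parameters the large-sample ΔFF AUC approaches the binormal
value Φ(Δμ/√(σ₁²+σ₂²)) ≈ 0.89; at the study size of 15/35 it
fluctuates around that value, which is why cohort-level checks are
framed as majorities over many seeded replicates rather than a single
AUC equality.

## Problem sizes and determinism

Tests and the acceptance script run noiseless segmentations on the
default desk-scale grid, 200-replicate IVIM noise studies, 100-replicate
cohort simulations, and an n = 2000 logistic recovery — sizes chosen so
the whole suite completes in well under a minute on one CPU while
leaving Monte-Carlo error comfortably inside the stated tolerances. All
stochastic components take explicit integer seeds (numpy
`default_rng`/`SeedSequence`), so every reported number is exactly
reproducible.

## Known limitations

* The segmentation's voxel-precision behaviour relies on the phantom's
  bimodal intensity structure; real studies have overlapping intensity
  distributions, and the Otsu split is then a genuine estimator, not an
  oracle.
* D* from 9-b-value ROI fits is the least stable IVIM parameter; its
  population values are not a validation target here (published tables
  of D* in marrow vary by orders of magnitude across studies and
  plausibly contain unit inconsistencies).
* The logistic model offers no penalization; with small cohorts and
  strong predictors separation is common and is surfaced as a flag
  instead of a fitted answer.
* DICOM ingestion, interactive viewing, inter-station harmonization and
  automatic skeleton detection are deliberately absent.
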