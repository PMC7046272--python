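# tdvpipe

Quantitative MRI response assessment for multiple myeloma: whole-body
diffusion-weighted tumour-burden volumetry, IVIM perfusion fitting, Dixon
fat-fraction quantification, and the cohort statistics that turn early
changes in these indices into response predictions.

## Who this is for

Researchers working with whole-body DWI and Dixon MRI of marrow disease
who need a tested, scriptable implementation of the common
"semi-automatic tumour volume + ROI biomarkers + ROC/logistic response
model" workflow — plus a synthetic-phantom module so every stage can be
validated with exact ground truth before touching patient data.

## What it computes

**Total diffusion volume (tDV).** From a multi-b-value DWI series the
pipeline fits the monoexponential model `S(b) = S0·exp(−b·ADC)` per
voxel, synthesizes a computed-DWI volume at b = 999 s/mm², and segments
disease in four steps: a fixed background threshold (97 on a min–max
normalized 0–255 scale), Otsu's between-class-variance binarization of
the remaining voxels, subtraction of a non-skeletal exclusion mask
(brain, nodes, bowel), and an ADC disease band
`0.55×10⁻³ < ADC ≤ 2.0×10⁻³ mm²/s` (the upper cut removes T2
shine-through). tDV is the surviving voxel volume in ml; mean ADC,
25th/75th percentiles, skewness and excess kurtosis summarize the mask.

**IVIM.** ROI-mean spinal DWI signal across 9 b-values (0–2000 s/mm²) is
fitted with the biexponential
`S(b)/S(0) = f·exp(−b·D*) + (1−f)·exp(−b·D)` by an alternated segmented
strategy, returning perfusion fraction `f`, pseudodiffusion `D*` and
tissue diffusion `D`.

**Fat fraction.** `FF = 100·fat/(fat+water)` voxelwise from Dixon
water/fat pairs, summarized over declared rectangular marrow ROIs with
protocol area validation.

**Response statistics.** Percentage changes `100·(follow-up −
baseline)/baseline`, exact Wilcoxon signed-rank tests, Mann–Whitney ROC
AUC with Hanley–McNeil (or DeLong) errors and Youden-optimal cutoffs,
sensitivity/specificity from confusion counts, a logistic response
model with odds ratios `OR = exp(β)`, and linear-weighted Cohen's kappa
for rater agreement.

**Synthetic data.** `tdvpipe.synthdata` generates whole-body phantoms
(skeletal marrow, focal/diffuse/combined lesions, high-ADC organs,
excluded bright structures, Rician noise), Dixon pairs with controllable
marrow FF, and two-group cohorts with configurable percentage-change
distributions — all with exact ground truth.

## Worked example

`examples/segment_phantom.py` builds a noiseless diffuse-involvement
phantom with exactly 201 ml of disease and runs the full chain:

```text
ground-truth tDV : 201.0 ml
recovered tDV    : 201.0 ml (25125 voxels)
  after background  : 28920 voxels
  after otsu        : 25637 voxels
  after exclusions  : 25514 voxels
  after adc_band    : 25125 voxels
mean ADC in mask : 1.00 x10^-3 mm^2/s
```

The stage counts show what each filter removed: the background threshold
keeps tissue, Otsu strips the dim uninvolved marrow, the exclusion mask
removes the bright brain stand-in, and the ADC band drops the high-ADC
organ — leaving exactly the 25125 involved voxels (× 8 mm³ = 201.0 ml).

`examples/ivim_fit.py` recovers marrow perfusion from ROI signal:

```text
perfusion fraction f : 0.247   (true 0.247)
pseudodiffusion D*   : 20.00 x10^-3 mm^2/s (true 20.00)
tissue diffusion D   : 0.350 x10^-3 mm^2/s (true 0.350)
converged: True, rss = 9.58e-14
```

The other examples cover fat-fraction change (`fat_fraction.py`: 56% →
40% gives −28.6%), the lower-ADC-threshold sweep (`threshold_sweep.py`)
and the full cohort report (`cohort_stats.py`).

A thin CLI mirrors the library for shell use:

```bash
tdv simulate --pattern diffuse_dominant --target-tdv-ml 201 --out phantom/
tdv segment --dwi phantom/dwi.nii.gz --bvals phantom/bvals.csv \
    --exclusion phantom/exclusion_mask.nii.gz --out seg/
tdv stats --cohort cohort.csv --out report/
```

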