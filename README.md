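# rsiscope

Automated, patient-level detection of clinically significant prostate cancer
(csPCa, histopathology grade group ≥ 2) from quantitative diffusion-weighted
MRI (DWI), for researchers evaluating quantitative imaging biomarkers against
radiologist interpretation.

Multiparametric prostate MRI is read qualitatively with the ordinal PI-RADS
score (1–5), which is reader dependent; the standard quantitative alternative,
the apparent diffusion coefficient (ADC), is unreliable when used fully
automatically. Restriction spectrum imaging (RSI) decomposes the DWI signal
into tissue compartments and yields a continuous biomarker — the RSI
restriction score (RSIrs) — that tracks restricted intracellular water, which
is elevated in dense tumor tissue. `rsiscope` implements the complete
patient-level analysis around that biomarker:

1. **Four-compartment fit.** Each voxel's direction-averaged signal across
   b-values (0, 500, 1000, 2000 s/mm²) is scaled by the median b = 0 signal in
   the prostate and fit as a nonnegative linear combination of exponential
   decays with fixed diffusion coefficients,

   S(b) = Σᵢ Cᵢ·exp(−b·Dᵢ),  D = (1.0e−4, 1.8e−3, 3.6e−3, ≫3.0e−3) mm²/s,

   using exact nonnegative least squares. The fitted restricted-compartment
   coefficient C₁ is RSIrs.
2. **ADC maps.** Mono-exponential log-linear fits from b = 0/1000
   (vendor-style two-point map) and b = 0/500/1000 (alternate map).
3. **Patient reduction.** Each patient becomes max RSIrs and min ADC over the
   prostate (or a zone) expanded by a uniform 5-mm Euclidean margin.
4. **Statistics.** Midrank ROC/AUC for RSIrs, ADC and PI-RADS; paired
   bootstrap (10 000 resamples) for confidence intervals and two-sided
   p-values on AUC differences; within–PI-RADS-stratum logistic posteriors
   concatenated into a combined PI-RADS + RSIrs score; per-category csPCa
   detection-rate tables.
5. **Synthetic cohort.** The clinical cohort is not publicly deposited, so a
   seeded generator produces DWI series, segmentations and labels whose
   statistical structure (grade-group marginals, per-PI-RADS detection rates,
   zone compositions, ADC-confounding benign tissue) matches the published
   tables, making the whole pipeline testable end to end.

## Worked example

```python
from rsiscope.cohort import CohortConfig, simulate_cohort
from rsiscope.pipeline import RunConfig, compute_markers
from rsiscope.stats import auc, pirads_stratum, stratified_posteriors

cohort = simulate_cohort(CohortConfig(n_patients=150, seed=0))
markers = compute_markers(cohort, RunConfig())
y = markers["cspca"].to_numpy(bool)

print("min-ADC AUC   ", round(auc(-markers["min_adc_vendor_whole"], y), 3))
print("max-RSIrs AUC ", round(auc(markers["max_rsirs_whole"], y), 3))
print("PI-RADS AUC   ", round(auc(markers["pirads"].astype(float), y), 3))
combo = stratified_posteriors(
    markers["max_rsirs_whole"].to_numpy(), y, pirads_stratum(markers["pirads"])
)
print("PI-RADS+RSIrs ", round(auc(combo.combined_score, y), 3))
```

prints

```
min-ADC AUC    0.46
max-RSIrs AUC  0.975
PI-RADS AUC    0.776
PI-RADS+RSIrs  0.903
```

Min-ADC sits near chance: the whole-gland minimum, searched through the 5-mm
margin, is dominated by low-signal periprostatic voxels and by benign
inflammation-like tissue with low ADC — the classic failure mode of fully
automated ADC. Max-RSIrs separates patients strongly because the restricted
fraction is an amplitude, not a ratio, and stays near zero wherever tumor is
absent. The stratified combination refines PI-RADS with within-category RSIrs
ordering and improves on PI-RADS alone.

The same pipeline is available from the shell:

```sh
rsiscope run-all --out results/        # full synthetic study, all tables
rsiscope simulate --out cohort/        # just the synthetic cohort (NIfTI + CSV)
rsiscope fit --dwi cohort/P0000/dwi.nii.gz \
  --prostate-mask cohort/P0000/mask_prostate.nii.gz --out maps/
```

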