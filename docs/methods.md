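# Methods

## The signal model

A direction-averaged diffusion-weighted voxel signal is modelled as a
nonnegative mixture of mono-exponential decays from four water compartments:

    S(b) = C1·exp(−b·D1) + C2·exp(−b·D2) + C3·exp(−b·D3) + C4·f(b)

with fixed diffusion coefficients D = (1.0e−4, 1.8e−3, 3.6e−3) mm²/s for
restricted intracellular, hindered extracellular and free water. The vascular
flow compartment has a coefficient much greater than 3.0e−3 mm²/s; since
exp(−500·0.03) < 10⁻⁶, it is modelled as an indicator contributing only at
b = 0 (f(0) = 1, f(b>0) = 0). This is numerically indistinguishable from any
sufficiently fast decay and keeps the 4 × 4 design matrix well conditioned
(condition number ≈ 112 at b = 0/500/1000/2000 s/mm²).

Signals are first scaled by the median b = 0 value inside the patient's
prostate mask, so coefficients are in normalized signal units and a voxel
whose fractions sum to 1 has unit b = 0 signal. The per-voxel fit is
nonnegative least squares: the model describes signal *contributions*, and
negative contributions are physically meaningless. An unconstrained fit is
available behind a flag for comparison. With four b-values and four
compartments the solver enumerates all column supports, solves each
unconstrained subproblem in closed form, and keeps the feasible candidate
with the lowest residual — exact, deterministic, and vectorised over voxels;
the test suite cross-checks it against an independent active-set solver.
Out-of-mask voxels carry NaN sentinels excluded from every reduction.

**RSIrs** is defined here as the fitted C1 map after median-b0 normalization.
Any further affine rescaling would be rank-invariant and leave every ROC
result unchanged. No spatial regularization or smoothing is applied; fits are
voxel-independent. The noise-map correction applied in clinical RSI
processing is not modelled; noise enters only through the simulator.

## ADC

ADC is the negative OLS slope of ln S(b) against b, in mm²/s. Two variants
are computed from the same series: a vendor-style two-point map (b = 0/1000,
where the slope reduces to ln(S₀/S₁)/1000) and an alternate three-point map
(b = 0/500/1000). A voxel with any non-positive signal in the subset is
flagged no-data rather than clipped: a −∞ log would otherwise silently win
every min-ADC reduction. ADC is invariant to positive rescaling of the
signal, so normalization order is immaterial.

## Patient reduction

Each patient is summarised by max RSIrs and min ADC over a search region:
the whole prostate, the peripheral zone, or the central gland (transition +
central zones). The region contour receives a uniform 5-mm margin, defined as
all voxels whose center lies within 5 mm Euclidean distance (in millimeters,
honoring the anisotropic 2.5 × 2.5 × 6 mm voxels) of a region voxel center,
computed with a sampled distance transform. The margin is applied to zone
masks as well as the whole gland, a uniform convention; both markers use the
same expanded region for symmetry. Negative patients are benign or grade
group 1; positives are grade group ≥ 2.

## Statistics

*AUC* is the midrank Mann–Whitney estimate — P(score⁺ > score⁻) + ½P(tie) —
so ordinal PI-RADS and continuous markers are treated identically and
complement symmetry (AUC(s) + AUC(−s) = 1) holds exactly.

*Bootstrap comparison*: patients are resampled with replacement 10 000 times;
both markers' AUCs are computed on identical indices; the 95% CI is the
2.5/97.5 percentile interval of the AUC difference; the two-sided p-value is
2·min(freq(Δ* ≤ 0), freq(Δ* ≥ 0)), floored at 2/(n_boot + 1). Resamples that
drew a single class are redrawn so the percentile grid stays fixed. With a
fixed seed the whole comparison is bit-reproducible. No multiple-testing
correction is applied; each pairwise comparison uses two-sided α = 0.05.

*Combination of PI-RADS and RSIrs*: within each PI-RADS stratum a univariate
logistic model of csPCa on max RSIrs yields posterior probabilities;
categories 1–2 are merged into the lowest stratum (too few patients for a
stable fit). The combined score is `stratum_index + posterior·(1 − ε)`, i.e.
the ROC is the concatenation of within-stratum segments in stratum order.
When a stratum has fewer than three patients of either class, or the fit
separates or fails to converge, the posterior falls back to within-stratum
marker midranks scaled into (0, 1) — ranks preserve the ROC, which is all
the analysis consumes. A pooled variant that ranks patients by posterior
alone is available (`combined_roc(..., pooled=True)`); the two coincide
whenever posteriors respect stratum order.

## The synthetic cohort

The generator emulates the study conditions the analysis assumes, not any
particular patient data:

* **Cohort structure.** Grade-group marginals default to the clinical counts
  (25, 40, 38, 20, 16, 12)/151; PI-RADS is drawn from class-conditional
  distributions derived from the published per-category detection counts, so
  expected detection rates match the published 40.0/14.8/45.5/84.4% at the
  cohort prevalence; lesion-zone probabilities are conditioned on csPCa
  status to match the zone subgroup compositions (103 peripheral, 37
  transition). All of these are config fields and can be overridden.
* **Geometry.** Ellipsoidal prostate (semi-axes 20 × 16 × 13 mm, ±8%
  per-patient scale) with an inner central-gland ellipsoid; the peripheral
  zone is the set difference, so the zones partition the gland exactly. Each
  patient with grade group ≥ 1 carries one ellipsoidal lesion clipped to its
  zone. The 24 × 24 × 12 grid at 2.5 × 2.5 × 6 mm keeps a full patient fit
  under ~10 ms while leaving room for the 5-mm margin.
* **Signal.** Tissue archetypes map regions to compartment fractions:
  peripheral-zone stroma (C1 = 0.04, ADC ≈ 2.0e−3), central-gland epithelium
  (C1 = 0.06, ADC ≈ 1.8e−3), tumor (C1 = 0.30 scaled by grade group from
  0.6× at GG1 to 1.2× at GG5, with C2 absorbing the difference), inflammation
  (C1 = 0.12, C2 = 0.80; ADC ≈ 1.4e−3), and dim fat-suppressed periprostatic
  tissue (fractions summing to 0.15). Per-voxel dispersion and a per-patient
  intensity factor (σ = 0.12) add biological spread. Noise is Rician: each
  b-volume is the arithmetic mean of its protocol direction count
  (2, 6, 6, 12) of independent magnitude draws at σ = 0.05, i.e. b = 0
  SNR ≈ 20 before averaging. A random scanner gain (200–600) makes the
  median-b0 normalization do real work.
* **Why min-ADC fails here.** Within this forward model a low-ADC tissue
  necessarily carries restricted signal (with C1 ≈ 0.1 the two-point ADC
  cannot fall below ≈1.4e−3 mm²/s), so the inflammation archetype alone
  cannot push min-ADC to chance. The decisive mechanism is the margin: ADC
  is a log-ratio, and in the dim periprostatic shell (signal ≈ noise at
  b = 1000) its per-voxel estimate has a standard deviation of ≈0.3e−3 and a
  deep lower tail, so every patient's whole-gland minimum is noise — exactly
  the failure mode that makes fully automated min-ADC unreliable in practice.
  RSIrs is an amplitude and stays near zero in those voxels. Both mechanisms
  were fixed from this forward analysis.
* **What the simulator does not model.** No k-space or coil simulation, no
  per-direction tensors or anisotropy, no distortion fields or their
  correction, no T2-weighted or contrast-enhanced series, no BPH nodules,
  biopsy artifacts or multifocal disease; PI-RADS is drawn conditionally on
  the label and is therefore independent of the images given the label.
  Passing end-to-end tests consequently demonstrates correctness and internal
  calibration of the pipeline, not clinical performance: the synthetic
  RSIrs AUC (≈0.97) is higher than is plausible in real cohorts because the
  archetypes are cleanly separated.

## Numerical choices

* NNLS support enumeration uses a feasibility tolerance of 1e−10 and prefers
  smaller supports on residual ties, making results deterministic.
* Ties in any marker are handled by midranks throughout; no jittering.
* Detection-rate cells with empty categories are reported as 0/0 with an
  undefined (NaN) rate; analysis subgroups missing a class are flagged
  not-estimable rather than filled.
* All randomness flows from explicit seeds through `numpy` `SeedSequence`
  spawning: per-patient streams in the simulator, per-comparison streams in
  the statistics, so adding a patient or an analysis never perturbs the
  others.

## Problem sizes

Default runs simulate 151 patients on the 24 × 24 × 12 grid and use 10 000
bootstrap resamples; the full pipeline completes in well under a minute on
one CPU. The statistical-calibration suites use 500 null cohorts (type-I
error of the AUC-difference test) and 300 cohorts with a known binormal AUC
difference (CI coverage), each of n = 150 with 2000 resamples.

## Known limitations

* The ADC-vs-RSIrs contrast depends on the archetype parameters; the package
  asserts the qualitative pattern (ADC near chance, RSIrs strong), not the
  published effect sizes, which arose from undeposited clinical data.
* The "vendor" ADC map is computed from the same simulated series restricted
  to b = 0/1000; a separately acquired clinical DWI series is emulated only
  through that b-subset choice.
* Lesion-level localization is out of scope; only patient-level reduction
  and discrimination are implemented.
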