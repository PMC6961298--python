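# mbdwi

Multi-b-value diffusion-weighted MRI (DWI) modelling for predicting
tumor response to radiochemotherapy — mono-exponential, intravoxel
incoherent motion (IVIM) and stretched-exponential model fitting,
volume-of-interest aggregation, diameter-based response classification,
and the cohort statistics that tie imaging biomarkers to outcome.

The package is aimed at quantitative-imaging researchers who want a
tested, reproducible reference pipeline for multi-b-value DWI biomarker
studies (the motivating application is cervical cancer), including a
synthetic phantom/cohort generator so every stage can be exercised and
validated without patient data.

## Models

For a voxel signal S(b) at diffusion weighting b (s/mm²):

* **Mono-exponential (Gaussian)** — `S(b)/S0 = exp(−b·ADC)`, fitted by
  ordinary least squares on the log signal.
* **IVIM bi-exponential** —
  `S(b)/S0 = (1−f)·exp(−b·D) + f·exp(−b·(D + D*))`, separating slow
  (true tissue) diffusion D from perfusion-driven pseudo-diffusion
  (D*, volume fraction f); fitted by bounded non-linear least squares
  with segmented initialisation (high-b log-linear fit for D) and
  optional full joint refinement.
* **Stretched exponential** — `S(b)/S0 = exp(−(b·DDC)^α)` with the
  distributed diffusion coefficient DDC and heterogeneity index
  α ∈ (0, 1]; α = 1 recovers Gaussian diffusion.

Per-patient values are aggregated over the tumor volume of interest as
the ROI-area-weighted mean `ΣAV/ΣA` across slices.  Patients are
classified CR/PR/SD/PD from longitudinal largest-diameter series
(CR at any visit within 12 months ends assessment; otherwise the
12-month diameter decides: PR for shrinkage > 30%, PD for growth ≥ 20%,
SD in between), with CR/PR forming the responder group.  The statistics
layer provides the pooled-variance t test, chi-square/Fisher tests,
Lin's concordance correlation coefficient for two-reader agreement,
empirical ROC with a Youden-index cutoff and DeLong confidence
interval, the DeLong paired AUC comparison, and the closed-form
binormal AUC used to validate the empirical ROC on simulation.

## Worked example

Fitting all three models to one noisy stretched-exponential voxel
(`examples/02_fit_voxel.py`, truth DDC = 0.972 × 10⁻³ mm²/s, α = 0.910,
SNR 100):

```
mono : ADC = 0.934 e-3 mm^2/s, R^2 = 0.9968
IVIM : D = 0.880, D* = 5.05, f = 8.3%, R^2 = 0.9995
SEM  : DDC = 0.969 e-3 mm^2/s, alpha = 0.894, R^2 = 0.9996
```

The stretched-exponential fit recovers the generating DDC and α within
a few percent and attains the best R²; the mono-exponential ADC is an
effective average over the heterogeneous decay.  The full pipeline on a
simulated 12 + 8 patient cohort (`examples/06_full_pipeline.py`)
reports group statistics on the fitted VOI values:

```
         parameter    responders non_responders  p_value
  alpha (unitless) 0.899 ± 0.044  0.519 ± 0.246   0.0001
DDC (10^-3 mm^2/s) 0.781 ± 0.164  1.206 ± 0.168   0.0000
```

Responders show lower DDC and higher α, and the fitted group means
track the generated truth to within ~1%.  The other examples cover the
forward models, VOI aggregation, response classification and the
cohort-statistics layer; each prints a short explanation of its output.

A thin CLI (`mbdwi simulate / fit / aggregate / classify / analyze`)
wraps the same library functions for shell pipelines over NIfTI volumes,
FSL-style `.bval` files and CSV tables.

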