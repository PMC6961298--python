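# Methods

## Signal models and units

All three decay models act on magnitude DWI signals over a b-value
scheme with per-b excitation counts (NEX).  The default scheme is the
12-b-value protocol b = 0, 10, 25, 50, 75, 100, 150, 200, 400, 800,
1000, 1500 s/mm² with NEX 1, 3, 3, 3, 3, 2, 2, 2, 2, 3, 5, 6.
Diffusivities are carried internally in mm²/s; the ×10⁻³ mm²/s
convention of published tables (and percent for the perfusion fraction)
is applied only at reporting time, which avoids silent thousand-fold
unit errors and keeps unit conversion exactly invertible.

The model equations are written on the normalised scale S(b)/S0, but
every fitter estimates an explicit S0 rather than dividing by the
measured b = 0 sample: once Rician noise is present, trusting a single
noisy b = 0 measurement would bias every parameter.

The IVIM perfusion compartment decays as exp(−b·(D + D*)).  Vendor
implementations differ on whether the pseudo-diffusion exponent
includes D; the alternative exp(−b·D*) convention is available via
`pseudo_diffusion_includes_d=False` in the fit configuration.

## Fitting

* **Mono-exponential**: ordinary least squares of ln S on b (slope
  −ADC, intercept ln S0).  Voxels with any non-positive sample are
  flagged unfittable rather than raising, mirroring the practice of
  excluding necrotic/cystic voxels from tumor ROIs; a non-positive
  slope estimate is returned with `converged=False`.
* **IVIM**: segmented first — D and S0·(1−f) from a log-linear fit over
  b ≥ 200 s/mm² (the largest "low" b in the scheme before the jump to
  400; at these weightings perfusion is essentially dephased), then
  (S0, f, D*) by bounded non-linear least squares with D fixed.  In the
  default full mode all four parameters are then refined jointly from
  the segmented start, with D* parameterised as D + δ, δ ≥ 0, so the
  slow/fast compartments cannot swap identity.  A D* pinned at its
  upper bound is flagged.
* **Stretched exponential**: bounded non-linear least squares over
  (S0, DDC, α) with α ∈ (0.01, 1], initialised from the mono fit with
  α = 0.9.

Bounds: ADC, D, DDC ∈ [10⁻⁵, 5×10⁻³] mm²/s; D* ≤ 0.1 mm²/s; f ∈ [0, 1].
These cover the physiologic range of pelvic tumors with wide margins.
Optimisation uses trust-region-reflective least squares with tolerances
1e-14 and at most 500 function evaluations; all starts are
deterministic (no random restarts), so voxelwise maps are bit-for-bit
reproducible.  Residuals are unweighted by default — the common vendor
behaviour — with optional √NEX weighting (inverse-noise-SD weighting
for NEX-averaged data) behind the fit configuration.

Goodness of fit is R² = 1 − SS_res/SS_tot on the untransformed signal
scale, undefined (NaN) for zero-variance signals.  Because α ≤ 1
includes α = 1, the stretched-exponential fit of a mono-exponential
signal can never have larger residual than the (nonlinear-scale) mono
fit; this nesting is enforced by a test.  Note that nesting compares
fits minimising the same loss: the production mono fitter minimises
log-scale error, so its R² on the signal scale can be marginally lower
than the SEM fit even on mono data.

## VOI aggregation

Per-patient biomarker values are the area-weighted mean ΣAV/ΣA of
per-slice ROI means.  Area is the non-NaN in-mask voxel count times the
in-plane voxel area (from the NIfTI header when reading images);
because the area scale cancels in the ratio, voxel counts and physical
areas give identical results.  Unfittable voxels are excluded from both
numerator and denominator rather than zero-filled.  The slice axis is
the third array axis, 0-based.

## Response classification

CR is detected as diameter ≤ ε at any visit within 12 months (default
ε = 0 mm; a small ε guards simulated measurement noise).  Otherwise the
visit nearest to month 12 decides (ties toward the earlier visit —
visits are quarterly, so a window rule is unnecessary): shrinkage
strictly greater than 30% is PR, growth of at least 20% is PD, SD
otherwise.  Patients with no visit at or before 12 months are excluded,
matching study practice of excluding early progressors and incomplete
treatments; interim PD therefore does not classify early.  Dual-reader
diameter disagreement is modelled upstream (the classifier consumes a
single consensus series).

## Statistics

* Group comparison: Student's pooled-variance two-sample t test by
  default (the convention of era-typical SPSS reports); Welch available
  by flag.  Significance threshold 0.05.
* Categorical covariates: chi-square test of independence, with
  automatic fallback to Fisher's exact test for 2×2 tables with any
  expected count < 5.
* Agreement: Lin's concordance correlation coefficient with population
  (1/n) moments; bands good (> 0.75), moderate (0.40–0.75, the
  boundary 0.40 assigned to moderate as the conventional banding leaves
  it unassigned), poor (< 0.40).
* ROC: empirical curve; AUC equals the normalised Mann–Whitney
  U statistic (ties counted ½).  The cutoff maximises Youden's
  J = sensitivity + specificity − 1, scanned over midpoints between
  adjacent observed values; ties in J break toward higher sensitivity,
  then the lower threshold.  Biomarker orientation (whether lower or
  higher values predict responder) is chosen so AUC ≥ 0.5 and is
  reported.  The 95% CI uses the DeLong variance (computed by the
  midrank formulation, O(N log N)) with a normal approximation.
* AUC comparison on the same patients: DeLong's paired z-test on the
  structural components.  The comparison method for paired AUCs is a
  documented package choice among standard options.
* `binormal_auc` gives the closed form Φ(|μ₁−μ₂|/√(σ₁²+σ₂²)) used as
  an analytic oracle for the empirical ROC on large simulated cohorts.
  On the default DDC group distributions it gives 0.974 — an upper
  reference for normally distributed biomarkers, intentionally distinct
  from what heavier-tailed real data would yield.

## Synthetic data

The generator emulates the structure of a 58-responder /
26-non-responder cervical-cancer cohort:

* **Biomarker truth** per patient is drawn from truncated normals with
  the group means ± SD of the emulated cohort (e.g. responders DDC
  0.831 ± 0.141 × 10⁻³ mm²/s, α 0.912 ± 0.043; non-responders DDC
  1.257 ± 0.167, α 0.612 ± 0.235), truncated at the model invariants
  (α ∈ (0, 1], f ∈ [0, 100]%, positive diffusivities); D* is kept above
  D.  Truncation means wide-SD parameters (non-responder α) have a
  generating mean slightly below the nominal location — recovery checks
  therefore compare fitted means with the means of the actually
  generated truth.
* **Signals** come from one designated forward model per cohort — the
  stretched exponential by default, as the best-fitting model of the
  motivating study; mono or IVIM cohorts are generated when those
  parameter families are under study, and the generating model is
  recorded in the dataset manifest.  Within-tumor heterogeneity is a
  per-voxel multiplicative jitter with 5% CV by default (patient-level
  dispersion is what published tables report; the within-tumor value is
  a modelling choice exposed in config).
* **Noise** is Rician (magnitude-image convention): the complex-channel
  SD at b is σ_b = S0/(SNR₀·√(NEX_b/NEX₀)), so higher-NEX acquisitions
  are proportionally less noisy and the near-zero high-b signal shows
  the characteristic positive Rician floor.  Default SNR₀ = 100.
* **Phantoms** are plain block masks (a centred square over 3 slices,
  27 tumor voxels by default), not anatomy.
* **Covariates** (tumor size class, FIGO stage, pathologic type,
  histologic grade, age) are drawn from the emulated cohort's printed
  group proportions.  Those printed responder tumor-size counts sum to
  40 rather than 58; the proportions are used as printed and the
  inconsistency noted here.
* **Trajectories** realise an intended CR/PR/SD/PD category on the
  quarterly visit grid (1.5, 3, 6, 9, 12, 15, 18 months) by linear
  drift to a 12-month diameter drawn safely inside the category's rule
  boundaries (CR: linear decline to 0 at a disappearance visit ≤ 12
  months).  Closure — every generated series classifies back to its
  intended category — is guaranteed by construction and verified on 500
  simulated patients.  The CR/PR split among responders (40/60) and
  SD/PD split among non-responders (80/20) are modelling choices.

What passing simulation tests shows — and what it does not: phantom
cohorts have exactly the assumed generating model, uniform block
geometry, no motion/eddy artefacts, no partial-volume mixing and no
registration error, so recovery there bounds best-case, not clinical,
performance.  In particular the empirical patient-level AUCs of real
cohorts reflect non-normal, correlated biology that the truncated
normal draws do not model.

## Problem sizes and determinism

Default verification sizes are chosen to run comfortably on one CPU:
84-patient cohorts at 27 voxels/patient for pipeline recovery and group
direction checks, 200 replicates per SNR level for noise-monotonicity,
10⁵ per group for the binormal ROC check.  Every generator output is a
pure function of (config, seed); dataset manifests record config, seed
and SHA-256 of each written file.

## Known limitations

* No preprocessing (denoising, motion/eddy correction, registration)
  and no tumor segmentation — masks are inputs.
* The IVIM fitter assumes the perfusion compartment is fully dephased
  above 200 s/mm² in the segmented stage; tissues with very low D*
  violate this (full-mode refinement mitigates it).
* Fitted-parameter maps are only as identifiable as the data allow:
  D* and f are weakly determined at moderate SNR, reflected in their
  wide bounds and flagging rather than hidden by constraints.
* The mean-signal model ranking of the motivating study (IVIM R² below
  mono R² on the same curve) is not reproducible by a converged nested
  fit and is not reproduced here; it likely reflects vendor-fitter
  instability.
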