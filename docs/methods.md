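# Methods

## The measurement model

The muscle fat index is a same-slice, same-side signal-intensity ratio:
psoas major (PM) mean over combined multifidus + erector spinae
("paraspinal") mean, on axial T2-weighted images. T2 signal rises with fat
content, and the PM is comparatively resistant to fatty infiltration, so the
ratio falls from ≈ 1 (lean paraspinal muscle) toward 0 (fat-replaced
paraspinal muscle). Raw ratios above 1.0 occur when the PM outshines the
paraspinal compartment without apparent PM infiltration; they are clipped to
1.0 and flagged (`was_clipped`) so every clip is auditable, never silent.

Region means are plain arithmetic means over labelled pixels. Pixels
carrying the epimuscular-fat label are removed from the paraspinal ROI
before averaging — fat outside the fascia is not muscle. Masks must be in
image space; no world-coordinate resampling is attempted. A configurable
floor (`minimum_roi_pixels`, default 25) rejects degenerate ROIs.

Key invariants, all tested: the MFI is exactly invariant to global intensity
scaling (the robustness argument for multi-scanner use); region means are
linear in the image and permutation-invariant; adding epimuscular pixels
next to a paraspinal ROI never changes that ROI's mean.

## Goutallier handling

Grades 0–4 (0 = no fatty streaks, 3 = equal fat and muscle, 4 = more fat
than muscle) are consumed as given, never inferred from images in the
analysis path. For regression they are trichotomised: category 0 = grade 0,
I = grade 1, II = grades 2–4 — higher grades are rare in practice, and the
merged category keeps the dummy-coded models estimable.

Per patient and vertebral level, the value entering regression is the
worst-case side: minimum clipped MFI, maximum grade. Ties in MFI record the
left side as source, purely for determinism. Levels use the upper-endplate
convention ("L2L3" = slice at the upper endplate of L3).

## Agreement statistics

**ICC.** Two-way random-effects, absolute-agreement, single-measures —
ICC(A,1): `(MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))` from the
subjects × raters ANOVA, with the McGraw–Wong F-distribution CI. A matrix
with zero total variance is defined as perfect agreement (ICC 1, CI [1, 1])
with a warning; zero residual variance with rater offsets collapses the CI
to the estimate, also flagged. The implementation is cross-checked in tests
against a brute-force sums-of-squares oracle (tolerance 1e-8) and against
`pingouin.intraclass_corr`.

**Gwet's AC1.** `(p_a − p_e) / (1 − p_e)` with per-subject average pairwise
agreement and `p_e = (1/(q−1))·Σ_k π_k(1 − π_k)`; chosen over kappa because
Goutallier prevalences are heavily skewed and kappa collapses under skew.
The CI uses Gwet's linearised variance with a t(n−1) reference, truncated to
[−1, 1]; no finite-population correction (the subject pool is treated as a
sample from an unbounded patient population).

**Bland-Altman.** Differences are taken in the supplied order; limits are
bias ± 1.96 × sample SD (n−1). Per-pair (mean, difference) coordinates are
exported for plotting; the package renders no figures itself.

**Complete-case rule.** A subject tuple (patient, level, side) enters an
agreement analysis only if every required cell exists: all observers'
session-1 readings (interobserver) or both sessions of one observer
(intraobserver). Dropped subjects are counted and reported.

**Interpretation bands.** The published verbal thresholds leave gaps (e.g.
nothing covers an ICC of 0.905 printed to three decimals); they are closed
as contiguous half-open intervals so every estimate gets exactly one label:
ICC poor < 0.50 ≤ moderate < 0.755 ≤ good < 0.905 ≤ excellent; AC1 poor
≤ 0.005 < slight ≤ 0.205 < fair ≤ 0.405 < moderate ≤ 0.605 < substantial
≤ 0.805 < almost perfect ≤ 1.

## Association models

Ordinary least squares per outcome (ODI 0–100, NRS back/leg 0–10, ZCQ
pain/disability 1–5, all treated as continuous), predictor either the
continuous MFI or Goutallier-category dummies against category 0, optionally
adjusted for age, sex (0/1), BMI and smoking (0/1). Listwise deletion with a
reported dropped count; minimum 10 complete cases; t-based 95% CIs and
two-sided p-values at α = 0.05. Standardised residuals and fitted values are
emitted as data for normality diagnostics rather than as a pass/fail check.

**AIC convention:** −2 × maximised Gaussian log-likelihood (MLE variance
RSS/n) + 2 × (mean parameters + 1 for the variance). Only within-outcome
differences on identical case sets are meaningful — the comparison refuses
differing n — and those differences are convention-invariant (tested via
outcome-shift invariance). The literature offers two conflicting rules of
thumb for "how big is a real AIC difference" (2–7 units vs a minimum of 6);
the verdict scale encodes both rather than adjudicating: |Δ| = 0 equivalent,
< 2 negligible, 2–6 meaningful, ≥ 6 strong. A numerically perfect fit
(RSS below 1e-12 of the outcome's total sum of squares) returns coefficients
with the AIC flagged undefined.

## Synthetic data: what it emulates, what it does not

**Phantoms.** Four elliptical muscle regions (PM left/right anterior,
paraspinal left/right posterior, mirrored across the midline) plus an
optional epimuscular fat rim, on a default 128 × 128 slice. Signal is a
linear two-compartment mixture `(1−f)·mu_muscle + f·mu_fat` with additive
Gaussian noise — the simplest model with an analytic truth. Defaults
mu_muscle = 400, mu_fat = 1000, noise_sd = 20 (5% of muscle signal),
background 60: arbitrary T2 units in realistic proportion (fat ≈ 2.5×
muscle on T2). Geometry is proportional to the image size and is checked
for bounds and overlap on every generation. Not emulated: real anatomy, 3D
volumes, bias fields, coil shading, partial-volume effects — so a green
phantom test establishes that the measurement chain is correct, not that
the index behaves on clinical images.

**Observers.** ROI jitter = random morphological erosion/dilation with
radius uniform in [−j, +j] (regenerated, bounded retries, if it would empty
the mask); epimuscular-rim inclusion with probability p models the plausible
violation of the exclusion rule; grade misreads shift ±1 with probability m,
reflected inward at the scale ends (the only reading under which a certain
misread of grade 0 yields grade 1). All observers read the *same* noisy
image, so with zero observer noise agreement is exactly perfect regardless
of image noise — by design, this isolates observer variance from scanner
variance.

**Cohorts.** Default n = 243; age ~ N(66.6, 8.5²), 49% female,
BMI ~ N(27.8, 4²), 23% smokers; MFI ~ Beta(3.55, 3.14) (mean ≈ 0.53,
sd ≈ 0.18), matching a surgical LSS population. Outcomes follow
`intercept + β_MFI·MFI + covariate terms + N(0, σ)` clamped to scale
ranges; default β_MFI per outcome are small negative effects of the size
seen univariately in such cohorts (ODI −6.9, NRS leg −1.58, NRS back −0.41,
ZCQ −0.3/−0.25), residual SDs match the observed outcome SDs, covariate
effects default to zero, and intercepts are set so each outcome mean sits
at its population value at MFI = 0.53.

The Goutallier grade is derived from the MFI through a fat-fraction
mapping: a piecewise-linear inversion sends MFI to an implied paraspinal
fat fraction, and fixed fraction edges (0.05 / 0.20 / 0.45 / 0.55 — grade 3
anchored at "equal fat and muscle") give the grade, optionally misread ±1
with probability 0.10 before trichotomisation. The inversion is calibrated
so the grade edges land at the MFI values observed per grade in LSS
patients (grade 0 ≈ 0.61 down to grade 4 ≈ 0.29), because a direct
two-compartment inversion with the phantom's constants cannot reproduce the
in-vivo joint distribution — in vivo the paraspinal and psoas baseline
signals differ, so an MFI of 0.53 coexists with mostly grade-0/1 muscle.
This calibration was fixed once, from those published summary values, and
is not a tuning knob.

## Pipeline and determinism

`run_pipeline` derives stage seeds from one master seed via
`numpy.random.SeedSequence.spawn`, so identical config + seed reproduces an
identical report payload byte for byte (no timestamps in the payload).
Configs are YAML or JSON; validation collects all problems into one
itemised error. Stage artifacts: measurement CSV, selected-values CSV,
grade-summary CSV, reliability JSON, Bland-Altman coordinate CSVs per
observer pair and per test-retest, cohort CSV, association table CSV,
`report.json` with provenance (config hash, version, seed) and record
counts (generated, clipped, dropped).

## Numerical choices and degenerate inputs

- Clipping is idempotent; clipped MFI ∈ (0, 1].
- Grade summaries use t-based CIs; a grade bucket with n < 2 is emitted
  with NaN CI rather than dropped.
- ICC CI bounds are clipped to [−1, estimate] / [estimate, 1] to absorb
  F-quantile round-trip error at the extremes.
- AC1 raises on p_e = 1 (all chance mass in one configuration) rather than
  returning 0/0.
- Zero/negative paraspinal mean, side mismatches, constant predictors,
  < 10 complete cases, and < 2 complete agreement subjects all raise with
  messages naming the offending quantity.

## Known limitations

- No automatic segmentation; masks are inputs (or synthetic).
- 2D single-slice only; no DICOM, no multi-echo/DIXON fat fraction.
- The observer model perturbs geometry and grades but not perception
  (no intensity-dependent bias, no learning effects between sessions).
- The cohort generator produces a stylised population: linear outcome
  models, independent covariates, no interactions, no missingness by
  default — adequate for validating estimator behaviour, not for power
  calculations in a real study.
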