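# Methods

This note documents the models implemented in `neocardio`, the calibration
of the synthetic cohort generator, the numerical choices made where the
design was open, and what the passing test suite does and does not
establish about real data.

## 1. Study design being emulated

The generator emulates a two-group neonatal echocardiography study:
preterm infants (*n* = 121, gestational age at delivery 33.9 ± 2.2 weeks)
and term controls (*n* = 134, 39.4 ± 1.3 weeks), each scanned soon after
birth (at 6.6 ± 5.4 / 4.0 ± 5.5 days of age) and again around 3 months
(99.1 ± 15.1 / 98.0 ± 13.8 days). A fetal arm supplies the growth
standard: 137 term-delivering reference pregnancies plus an overlap subset
of the neonatal cohort (10 preterm, 45 term) scanned from 15 weeks of
gestation, with 1–5 scans per fetus drawn from the observed frequency
distribution (110:43:21:12:6 out of 192).

All sampled echo quantities (mass and volume indices, wall thicknesses,
TAPSE, tissue-Doppler velocities and their ratios) use group- and
stage-specific normal distributions whose means and SDs are the printed
cohort values; draws are truncated two-sided at mean ± 4 SD and floored at
physiologic minima so every measure is strictly positive. End-diastolic
and end-systolic volume indices are drawn jointly (correlation 0.9,
resampling the rare pairs with ESV ≥ 0.98·EDV or ESV ≤ 0.05·EDV) so that
derived ejection fractions are physiologic; EF itself is derived, not
sampled, and its group means (≈58 / ≈64 % at birth) are emergent.

Two printed values required judgement: the birth LV EF SD is printed as
"59 (80)", which we read as a typo for SD 8 (every other EF SD in the
table is 7–13); and LVIDd, needed by the linear-mass formula, has no
printed cell, so nominal neonatal values (1.7/1.9 cm at birth, 2.4/2.5 cm
at follow-up, SD 0.2–0.25) are used and documented as invented.

## 2. Gestational-age effect on postnatal mass accrual

Per-infant percent change in ventricular mass index from birth to
follow-up is modelled as Δ% = α + β·GA + ε with ε ~ N(0, σ_ε²). Given
target group means (m_pre, m_term), the GA mixture (means, SDs, preterm
weight w) and a target population correlation r, the closed form

    β   = (m_pre − m_term) / (GA_pre − GA_term)
    α   = m_pre − β·GA_pre
    σ_ε = |β| · σ_GA,mix · sqrt(1/r² − 1)

makes the group means exact and the population correlation equal to r
(`solve_ga_effect`). A target r whose sign conflicts with β is infeasible
and raises.

GA itself is sampled from truncated normals — preterm on [24, 37) weeks,
term on [37, mean + 4 SD) — with the *location* parameter solved so the
truncated mean equals the printed group mean. Because truncation also
shrinks the SD, `default_calibration()` feeds the realised truncated SDs
(1.820 and 1.189 weeks) into `solve_ga_effect`; with the printed
(untruncated) SDs the generated-population correlation would land at
≈ −0.474 instead of the −0.49 target. The follow-up mass index is then
birth index × (1 + Δ%/100), with Δ% capped below at −95 % so the index
stays positive; the cap binds with probability < 10⁻³ and moves the group
means by ≪ 0.01 percentage points.

Consequences worth knowing:

* The within-group SD of Δ% is emergent, ≈ 32 % in both groups, versus
  printed values of 41.9/29.4 (LV) and 38.1/40.8 (RV). A single (β, σ_ε)
  pair cannot match two group means, one correlation *and* two group SDs;
  we prioritise the means and the correlation.
* Follow-up mass-index group means are emergent products
  (birth mean × mean growth factor): ≈ 29.7/26.4 g/m² for the LV against
  printed 29.2/26.0 — within sampling noise of a 100–120-infant group.
* Whether the published correlation was computed over both groups combined
  or within the preterm group alone is not stated; we calibrate the
  combined-cohort correlation.

## 3. Body size and covariates

* **BSA** uses the weight-only Boyd form, BSA = 0.0004688·W^(0.8168 −
  0.0154·log₁₀W) with W in grams. Chosen because infant length is rarely
  measured reliably; evaluated at the cohort's mean weights (2053, 3315,
  4960, 6051 g) it reproduces the printed mean BSAs (0.16, 0.23, 0.30,
  0.35 m²) at two decimals.
* **Head circumference** follows a Gompertz curve in postmenstrual age,
  hc(t) = 47·exp(−exp(−0.0592·(t − 20.4))) cm plus a subject-level offset
  (SD 1.2 cm) and visit noise (SD 0.3 cm), which lands within ~0.4 cm of
  the printed birth and 3-month means and gives a plausible 15-week fetal
  HC (~12 cm). HC is forced strictly increasing along each subject's visit
  sequence (cumulative maximum plus a 0.001-cm tie-break), since its only
  role is as a monotone growth indicator usable across the birth
  transition.
* **Birthweight** is drawn per group with a within-group GA slope
  (150/120 g per week) and residual noise chosen to keep the printed total
  SD; birthweight z-scores are drawn with the printed group means/SDs and
  correlate ~0.5 with the weight residual. Antenatal steroids are sampled
  at the group rates (77 % vs 0.7 %), making them nearly collinear with
  prematurity, as in the emulated design; other covariates (cesarean,
  hypertension, sex, twins, 5-minute Apgar) are sampled independently at
  their printed rates.

## 4. Fetal mass trajectory and the growth standard

Fetal ventricular mass follows ln m = b₀ + b₁·ln t + b₂·t with
coefficients (−18.817, 6.432, −0.084) chosen so LV mass is 0.07 g at 15
weeks and 4.7 g (the term-birth mean) at 40 weeks, plus a subject random
intercept (SD 0.12 on the log scale) and visit noise (SD 0.10). The RV
runs a constant log-offset below the LV matching the term-birth RV/LV mass
ratio (4.1/4.7). This is an invented but documented trajectory: it makes
the fetal and postnatal arms mutually consistent at 40 weeks, which is the
property the centile machinery needs.

The centile standard fits ln(outcome) as a fractional polynomial of
postmenstrual age: degree 2, powers searched exhaustively over the
standard set {−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 denoting ln t; a repeated
power p contributing t^p and t^p·ln t), least squares, lowest Gaussian
deviance wins, ties broken toward the linear powers then lexicographically.
The residual SD is constant on the log scale by default — the log
transform is what stabilises the variance — with a degree-1 FP variance
model available behind `sd_model="fp"`. Repeated measures are handled by a
between/within moment decomposition: the subject intercept variance σ_u²
is max(0, var(subject mean residuals) − σ_e²·mean(1/n_i)), subject BLUPs
shrink by σ_u²/(σ_u² + σ_e²/n_i), the mean curve is refit on
intercept-centred data, and centiles use √(σ_u² + σ_e²). Full-likelihood
mixed modelling was deliberately avoided; on data with no subject-level
variance the two coincide, and the moment estimator recovers simulated
components within 15 % at 200 subjects × 3–4 visits.

Centiles never extrapolate beyond the fitted age range unless explicitly
asked (`extrapolate=True`); the pipeline uses that flag only for the
49-week comparison of the preterm and term median curves.

One known mismatch with the emulated study: because the generator draws
birth mass *indices* independently of the fetal trajectory, the
cross-sectional spread of preterm birth masses against the fetal standard
is wider (z SD ≈ 1.5) than a longitudinally tracked cohort would show
(published z SDs ≈ 0.5). The z *means* are near zero, as expected. Tests
of the centile machinery therefore run against simulated data from a known
standard, not against the cohort generator.

## 5. Ventricular contours and the shape model

Contours are a parametric stand-in for traced four-chamber borders. The
endocardium is a superellipse |x/(W/2)|^m + |y/b|^m = 1 kept above the
annulus chord — the chord of width a·W sitting below the equator, so the
annulus is narrower than the mid-ventricular width — traversed corner →
apex → corner. A single globularity parameter g ∈ [−1, 1] drives both the
length/width ratio (1.55 − 0.35g: 1.2 at g=+1 "globular", 1.9 at g=−1
"conical") and the exponent (2.0 + 0.4g). The semi-axis b is solved so the
apex-to-chord length over the maximal width equals the target ratio
exactly; after arc-length resampling the nearest samples are snapped onto
the analytic apex and equator so that this identity also holds on the
discrete point set. The epicardium is the outward-normal offset by the
wall thickness (normals from the implicit-function gradient). I.i.d.
Gaussian point noise is added last; a self-intersecting draw is retried
(≤ 10 times). Default shape parameters: preterm birth g = 0.6, term birth
g = −0.2 (the group contrast), both groups g = 0.1 at follow-up
(convergence); subject-level g SD 0.25; sizes 1.25/1.45 cm maximal width
at birth growing to 1.85/1.95 cm; wall 0.30 cm; point noise 0.02 cm.

The shape pipeline: 50-point arc-length correspondence with three anchor
landmarks (two annulus corners, apex); generalized Procrustes with
translation and rotation only (scale retained, so overall size emerges as
principal mode 1, and size-free analysis is achieved by *dropping* mode 1
rather than pre-scaling); PCA of the aligned coordinates with modes
oriented so the loading on overall scale is positive; Welch t-tests per
mode under three conditions (birth, follow-up, follow-up − birth
"growth"); and a Fisher discriminant w = (Σ_pooled + εI)⁻¹(μ_pre − μ_term)
over standardized scores of a mode subset, ε = 10⁻⁶·trace/dim, threshold
at the projected-mean midpoint, oriented so preterm scores higher. Nested
subsets {2}, {2,3}, … are scored by leave-one-out AUC (Mann–Whitney rank
statistic, ties averaged) and the smallest subset within 0.005 of the
maximum is selected. Because the parametric family has essentially two
degrees of freedom (size and globularity), the group contrast concentrates
in mode 2 and the selector typically returns {2}; the subset-recovery test
instead injects signal directly into score space (modes 2–6) to exercise
the selection logic. Follow-up separation is assessed by projecting
follow-up shapes onto the *birth-trained* discriminant axis, which avoids
resubstitution bias in the null condition.

## 6. Statistics layer

Group comparisons use Welch's t-test by default (the emulated tables show
unequal variances); Student's and Mann–Whitney (exact enumeration for
tie-free samples with both n ≤ 20, otherwise the tie-corrected normal
approximation) are available. Pearson χ² is computed without continuity
correction (Yates behind a flag). Forced-entry OLS enters all predictors
simultaneously and raises on rank deficiency, naming the collinear
columns — the steroids/prematurity collinearity in generated cohorts
triggers exactly this path. The minimal detectable standardized difference
uses the normal approximation d = (z₁₋α/₂ + z_power)·√(1/n₁ + 1/n₂),
giving 0.351 SD for n = 134/121 at α = 0.05, power 0.80; a noncentral-t
variant sits behind `exact=True`. No multiple-testing correction is
applied anywhere. The random-intercept regression uses the same moment
decomposition as the centile module with quasi-demeaning GLS for the fixed
effects.

## 7. Problem sizes, seeds, determinism

All randomness flows from a single integer seed through
`numpy.random.default_rng`; a fixed (config, seed) pair reproduces
byte-identical CSV outputs and file hashes. The calibration-recovery
checks run at 50,000 infants per group (sampling SE of a group-mean
percent change ≈ 0.15, so the 3·SE acceptance band is ≈ ±0.45 percentage
points); centile coverage at 10,000 simulated points; shape separation at
the study's own 121/134; oracle equivalences on ≤ 20-shape instances.
These sizes keep the full suite under a minute of compute while leaving
the Monte Carlo bands well clear of the tolerances.

## 8. Known limitations

* The generator is cross-sectionally calibrated; it does not model
  within-infant tracking between birth indices and the fetal trajectory,
  diurnal or inter-observer measurement error structure, missing-data
  patterns, or the stratified recruitment of the emulated study.
* Contours are a two-parameter family; real traced borders carry regional
  wall variation the shape model would pick up as additional modes.
* The area–length mass/volume formulas inherit their single-plane
  geometric assumptions; no biplane or disk-summation variants are
  provided.
* Passing tests demonstrate that the pipeline recovers the structure the
  generator encodes — they are parameter-recovery and oracle-equivalence
  results, not clinical validation on real echocardiograms.
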