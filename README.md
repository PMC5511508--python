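# neocardio

Tools for studying **disproportionate postnatal cardiac hypertrophy in
infants born preterm**: a calibrated synthetic-cohort generator, the
echocardiographic derivation formulas, fractional-polynomial growth
centiles for fetal-to-postnatal ventricular mass, a 2D statistical shape
model of the four-chamber left ventricle, and the cohort statistics layer —
wired into one reproducible pipeline.

The package is aimed at researchers in neonatal cardiology and
biostatistics who want to prototype, power, or teach this kind of analysis
without access to patient-level echo data. Every stage runs on synthetic
cohorts whose statistical structure (group sizes, gestational-age
distributions, echo means/SDs, the gestational-age dependence of postnatal
mass accrual, and a globular-vs-conical ventricular shape contrast) is
calibrated to a two-group neonatal study design: *n* = 121 preterm infants
(GA 33.9 ± 2.2 weeks) and *n* = 134 term infants (39.4 ± 1.3 weeks) scanned
at birth and at 3 months, with fetal reference scans from 15 weeks of
gestation.

## The models

**Gestational-age effect on mass accrual.** Per-infant percent change in
ventricular mass index (mass/BSA, g/m²) from birth to 3 months follows

    Δ% = α + β·GA + ε,   ε ~ N(0, σ_ε²)

with (α, β, σ_ε) solved in closed form so that the preterm and term group
means and the population correlation r(GA, Δ%) equal their calibration
targets exactly (`solve_ga_effect`): β = (μ_pre − μ_term)/(GA_pre −
GA_term), σ_ε = |β|·σ_GA·√(1/r² − 1). Defaults target Δ% = 57.8 vs 27.3 %
(LV), 39.3 vs 16.6 % (RV), r = −0.49 (LV) and −0.37 (RV).

**Echo derivations.** BSA by the weight-only Boyd formula
(0.0004688·W^(0.8168−0.0154·log₁₀W)); LV mass from linear measures
(0.8·1.04·[(IVSd+LVIDd+PWd)³−LVIDd³]+0.6); single-plane area–length
volumes (V = 8A²/3πL); shell mass = 1.05 g/ml × (epicardial − endocardial
area–length volume); EF, SV, E/A, E/E′, and BSA- or HC-indexed variants.

**Growth centiles.** ln(mass) is fit as a degree-2 fractional polynomial
of postmenstrual age (powers from {−2, −1, −0.5, 0, 0.5, 1, 2, 3}, 0 = log)
with constant log-scale residual SD; centile_p(t) = exp(μ(t) + z_p·σ) and
z = (ln y − μ(t))/σ. Repeated scans per subject enter through a
between/within moment decomposition with a subject-level random intercept.

**Shape model.** Contours are resampled by arc length, aligned by
generalized Procrustes (scale retained so size emerges as mode 1), and
decomposed by PCA. Size (mode 1) is set aside; nested subsets of the
remaining modes are combined by a regularized linear discriminant scored by
leave-one-out cross-validated AUC (Mann–Whitney statistic).

## Worked example

```python
from neocardio import default_calibration, generate_cohort, derive_table, pearson_r
from neocardio.pipeline import percent_changes, summarize_table2

cfg = default_calibration()          # group sizes, echo means/SDs, GA effect
cohort = generate_cohort(cfg, seed=7)
derived = derive_table(cohort.table())
pct = percent_changes(derived[derived["cohort"] == "neonatal"])

pre = pct[pct.group == "preterm"]; term = pct[pct.group == "term"]
print(f"preterm dLVMI%: {pre.dlvmi_pct.mean():.1f} +/- {pre.dlvmi_pct.std():.1f}")
print(f"term    dLVMI%: {term.dlvmi_pct.mean():.1f} +/- {term.dlvmi_pct.std():.1f}")
r = pearson_r(pct.ga_birth.to_numpy(), pct.dlvmi_pct.to_numpy())
print(f"corr(GA, dLVMI%): r={r.estimate:.2f}, p={r.p_value:.2g}")
```

prints (for this seed)

```
preterm dLVMI%: 59.3 +/- 33.2
term    dLVMI%: 29.9 +/- 30.8
corr(GA, dLVMI%): r=-0.53, p=1.5e-19
```

i.e. at a realistic sample size the preterm group roughly doubles the term
group's postnatal gain in LV mass index, and the gain grows with the degree
of prematurity. `summarize_table2(derived)` tabulates every echo measure as
group × stage mean (SD) with significance flags; at this seed the LV mass
index row reads 19.06 (3.94) vs 21.41 (3.74) g/m² at birth (preterm lower,
p < 0.001) and 30.26 (8.77) vs 27.84 (8.02) at follow-up (preterm higher,
p < 0.05) — the crossover that motivates the analysis.

The full pipeline (cohort → derived table → centile standards → shape
model → statistics, with per-file SHA-256 hashes for reproducibility) runs
from the shell:

```bash
phg run --config cfg.json --seed 7 --out results/
```

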