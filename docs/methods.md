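# Methods

## Problem and model

`iodapport` estimates where a population's dietary iodine comes from when the
food base is iodine-poor. Three additive sources are modelled:

* **food** — per-capita supply of each food item (FBS-style accounting,
  g capita⁻¹ d⁻¹) multiplied by its iodine concentration on a dry-weight
  basis;
* **iodised salt** — salt mass × salt iodine concentration × (1 − cooking
  loss); iodine in salt is volatile, and losses from production to cooking of
  up to ~90% are reported, so the loss fraction is an explicit scenario knob
  (default 0, so headline numbers are production-level);
* **drinking water** — volume × concentration, with 2 L d⁻¹ the conventional
  adult assumption.

The total is compared with population reference values (EAR 64/107/143,
RNI 120/150/200 μg d⁻¹ for children/adults/pregnancy; adult TUL 600 μg d⁻¹ in
the EU convention, 1,100 in the US one). Classification is interval-based and
monotone: below_EAR < EAR_to_RNI < adequate < above_TUL, with `adequate`
closed at both ends (RNI ≤ total ≤ TUL).

Iodine status is read from urinary iodine concentration (UIC) in casual
samples, optionally divided by creatinine to correct for urine dilution. The
corrected value (μg g⁻¹ creatinine) is treated as numerically commensurate
with the μg L⁻¹ cut-offs, as is standard in survey tables; a rescaling by an
expected daily creatinine excretion would change individual values but not
the package's machinery, and is deliberately not applied.

## Statistical conventions

* **Censoring.** Values below the limit of detection (solid LOD
  0.01 mg kg⁻¹, liquid 0.25 μg L⁻¹, both overridable) are substituted at
  LOD/2. Substitution triggers on the explicit flag *or* on a value below the
  LOD, because input files may carry "<x" strings converted upstream. The
  operation is idempotent.
* **Quartiles.** All median (Q1, Q3) reporting uses linear interpolation
  between order statistics (numpy's default, the "type 7" rule). The
  convention matters at small n (the salt group has n = 5).
* **Signed R².** Soil–iodine correlations are reported as sign(r) × r², the
  convention of the applied soil literature (a negative printed "R²" denotes a
  negative correlation); the plain Pearson r is reported alongside in
  `correlation_report` because signed R² is statistically unorthodox.
* **Group comparisons.** One-way fixed-effects ANOVA on log10-transformed
  concentrations (scipy `f_oneway`), with per-group geometric means
  back-transformed from the log scale. The F statistic is invariant to
  rescaling all concentrations by a positive constant.
* **Quadrants.** "High pH"/"high OM" means strictly above the dataset median;
  ties go low. Medians are recomputed per dataset.
* **Rounding.** Group shares and category proportions are reported to the
  nearest integer percent; intake contributions to 0.1 μg; headline totals
  additionally to the nearest 10 μg.
* **Boundary choices.** UIC categories are left-closed/right-open with severe
  excess at ≥ 300 (published band edges overlap, e.g. "100–200" and
  "200–300"); adequately iodised salt is ≥ 15 mg kg⁻¹ (the stricter ">15"
  variant appears in places; the inclusive boundary follows WHO usage).

## Fresh weight vs dry weight

Composition data are dry-weight; FBS supplies are fresh-weight. Moisture
factors are survey-specific and inventing them would contaminate the results,
so the conversion is an explicit per-item input `dw_fraction` with default
1.0 (supply already on the composition basis). Users with real FBS data
should supply per-item dry-matter fractions.

## Synthetic-data generator

All concentration variables are log-normal — positive, right-skewed, and
consistent with the log10 ANOVA transform. Geometric SDs are calibrated from
printed quartiles via `sigma = ln(Q3/Q1)/(2 × 0.6745)`:

| dataset | default calibration |
|---|---|
| leafy vegetables | median 0.155 mg kg⁻¹, σ_ln 0.78, n 151 |
| maize grain | median 0.01 (at the solid LOD), σ_ln 1.0, n 82 |
| roots/tubers | median 0.008, σ_ln 1.0, n 27 |
| fish | median 0.51, σ_ln 0.63, n 12 |
| salt | median 53.1 mg kg⁻¹, σ_ln 1.21, n 5 |
| water | median 12.6 μg L⁻¹, σ_ln 1.78, n 19 |
| soils | total I median 2.06 (1.18, 3.35), n 92; signed R² +0.57 with log OM, −0.27 with pH; water-extractable fraction Beta with median ≈ 1.3% |
| urine | two sites n 59 + 59; corrected-UIC lognormals solved from the per-site category mixes (medians ≈ 181 and 214, σ_ln 0.674 and 0.464); creatinine lognormal median 1.1 g L⁻¹, σ_ln 0.5, independent |
| FBS | 92 items; group masses = printed group iodine supply ÷ group median, so the true-parameter supply is 7.8 μg capita⁻¹ d⁻¹ with shares 40/33/14/8/4/1% |

The maize quartiles are printed inconsistently in the source survey (median
0.01 with Q3 0.009), so the maize σ_ln is set from the order of magnitude of
the printed grain range instead; no special-casing is applied downstream.

Soil total iodine is generated as
`log10(I) = log10(2.06) + 0.336 · (0.755 z_OM − 0.520 z_pH + 0.400 ε)` with
standardised log-OM, standardised pH (uniform on 4.8–8.5) and standard normal
noise, giving the configured signed R² values in expectation. FAO classes are
drawn consistently with pH (calcareous classes concentrate above pH 6.5), and
~5% of soils are Leptosols (unassignable).

Censored food values are emitted with the flag set and the value blank, so
the pipeline's half-LOD substitution is exercised end to end. One global seed
feeds fixed per-generator sub-streams (`numpy.random.SeedSequence` spawn
keys), so adding a generator never perturbs existing outputs; identical
config + seed gives byte-identical files.

**What the generator does not emulate:** spatial structure (no geography,
no soil–plant pairing by distance), within-subject UIC variation (single
sample per person), correlated measurement error, seasonality, and any
soil→crop iodine transfer (deliberately: the survey found none). Passing
recovery tests therefore show the pipeline is correct and well calibrated on
data matching its distributional assumptions — not that those assumptions
hold in any particular field dataset.

## Validation design

* **Oracle equivalence.** Quartiles, signed R² and category proportions are
  checked against independent brute-force implementations (order-statistic
  interpolation from scratch, covariance-formula correlation, direct
  counting) on 200 random instances each.
* **Parameter recovery.** A single sample median at the survey sizes
  (n = 82–151) with the calibrated geometric SDs has ~8–14% relative sampling
  SD, so a one-draw check at a 5% tolerance would be uninformative. Recovery
  is instead assessed over 50 seeded replicate datasets at the default sizes:
  the mean recovered leafy-vegetable median must be within 5% relative
  (Monte-Carlo SD ≈ 1.1%), the mean soil OM–iodine signed R² within ±0.05 of
  +0.57 (MC SD ≈ 0.01) and the mean pooled corrected UIC category proportions
  within ±2.5 pp of the generating lognormal CDF (MC SD ≤ 0.65 pp) — ~3–5
  sigma bands fixed from theory before the tests were first run.
  Maize is excluded from median recovery: its true median sits exactly at the
  LOD, so about half of each sample is censored and whenever censoring
  exceeds 50% the sample median collapses to the half-LOD value. That is a
  property of the estimand under censoring, not of the implementation; the
  maize check asserts the ≈50% censoring rate instead.
* **ANOVA calibration.** Under the null (two groups from one log-normal,
  n = 30 each) the rejection rate at α = 0.05 over 1,000 simulations must be
  5% ± 1.5 pp; a 2σ-shift alternative must be detected in ≥95% of runs.
* **Determinism.** `run-all` on the demo dataset is byte-identical across
  reruns with the same seed; report files contain no timestamps by design.

Problem sizes throughout the suite (50 replicates, 1,000 null simulations,
200 oracle instances) were chosen as the smallest sizes at which the
Monte-Carlo error is negligible relative to the asserted tolerances.

## Known limitations

* Half-LOD substitution biases low-concentration summaries; maximum-likelihood
  censored estimators (e.g. lognormal MLE with censoring) would be preferable
  for heavily censored groups but are outside the package's reporting
  conventions.
* Intake is a deterministic scenario model, not a usual-intake distribution;
  no between-person variance or probabilistic adequacy prevalence is
  estimated.
* Creatinine correction is plain division; specific-gravity or osmolality
  corrections are not implemented.
* Single-sample UIC designs cannot separate within- from between-person
  variation; population calls rest on group medians (n > 30 advised, ≥ 300
  recommended — the package warns below both).
* The FBS pathway inherits the weaknesses of balance-sheet accounting
  (national means, no demographic disaggregation, fish supply likely
  understated relative to household surveys).
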