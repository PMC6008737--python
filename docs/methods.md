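# Methods

## The scoring model

APACHE II assigns each of 12 physiologic variables 0–4 points by the worst
(most abnormal) value in the first 24 h, using piecewise interval tables;
the Glasgow Coma Scale contributes `15 − GCS` points, age 0–6 points and
chronic health 0–5 points, for a total of 0–71. The engine here is entirely
table-driven: the interval tables live in
`src/apmscore/data/apache2_tables.yaml` (half-open `[low, high)` bands, the
top band closed; exactly one zero-point "normal" band per variable), with a
SHA-256 recorded in `severity.py` and verified on load so the transcription
cannot drift silently. Two conventions needed fixing where the printed
score sheet is ambiguous:

* **Interval convention.** Score-sheet bands like "55–60 / 61–70" leave the
  interior open; we use half-open intervals meeting at the printed lower
  bounds (e.g. PaO2 `[55, 61) → 3`, `[61, 71) → 1`), which partitions the
  domain unambiguously and preserves every printed boundary value's points.
* **Worst-value ties.** When two readings score equal points, the one
  farther from the midpoint of the zero-point band wins, then the earlier
  reading. This only matters for exact ties and makes the engine
  deterministic.

Out-of-domain readings clamp to the extreme band rather than erroring,
since the domains already extend beyond physiologic plausibility. Missing
variables raise a named error; there is no silent "normal if unmeasured"
imputation.

APACHE III totals (0–299; acute physiology 0–252, age 0–24, chronic health
0–23) are accepted as validated inputs only — the 1991 physiologic
sub-score tables are out of scope.

## APM weighting rules

APM thickness `t` (mm) is the average of three consecutive caliper
readings, rounded half-away-from-zero to integer mm before scoring (the
raw mean is kept for the risk-curve stage; rounding is configurable since
score sheets work in integer points).

* **Linear anchor rule** (APACHE II composite): a multivariable logistic
  fit of death on `t` plus physiologic controls is compared against the GCS
  per-point coefficient after sign alignment; "close" means a relative gap
  ≤ 25% of the larger magnitude (the tolerance is a package choice — no
  standard exists — and is configurable). When close, APM is scored
  `max(0, anchor − t)` with the anchor at the cohort median (15 mm),
  mirroring how GCS enters APACHE II. Composite range 0–86 (engine maximum
  71 + rule maximum 15).
* **Categorical rule** (APACHE III composite): the death-probability curve
  over `t` is a univariate logistic fit evaluated on the integer-mm grid,
  with per-mm empirical rates retained; under complete separation it falls
  back to empirical rates with a warning. The upper cutpoint is the cohort
  median; the lower cutpoint is the grid point of maximal |slope| below the
  median (the fitted curve's 50% crossing), reproducing the 10 mm cut; both
  are overridable. Category weights are the odds ratios of the HIGH
  (t ≤ 10) and MID (10 < t ≤ 15) indicators versus the REF (t > 15)
  reference, rounded to the nearest integer (half away from zero; a
  truncate option exists). Weights must be non-increasing HIGH → REF and a
  non-reference OR < 1 is an error: a protective category cannot receive
  positive points.

The boundary t = 15 mm belongs to MID, consistent with the linear rule
giving 0 points at 15 and positive points strictly below.

Because printed category ORs from small cohorts are estimation-sample
sensitive (the crude cross-product OR from the published group counts is
55.7 for HIGH where 40.7 is printed, and the HIGH column's n is internally
inconsistent), the shipped `PAPER_DEFAULT_WEIGHTS = (40, 7, 0)` are a
constant with provenance `paper_default`, never re-derived; fitted and
crude ORs are always reported side by side.

## Logistic regression and ROC machinery

`fit_logistic` is maximum likelihood via Newton scoring (statsmodels
`Logit` under the hood) with Wald CIs `exp(B ± z·SE)`; complete or
quasi-complete separation raises a named error (detected from runaway
coefficients |B| > 25 or SE > 10³). AUC uses midrank tie handling; its
variance and the paired test for two correlated AUCs use DeLong structural
components (`V10` per death, `V01` per survivor). AUC orientation defaults
to *raw*: an inversely oriented predictor such as APM is reported with
AUC < 0.5 rather than silently flipped, and `auc(−s) = 1 − auc(s)` holds
exactly. P-values are reported to 4 decimals with no multiplicity
correction. Degenerate comparisons (identical rank vectors) return
ΔAUC = 0 with p = 1 rather than 0/0.

## The synthetic cohort generator

The generator emulates the cohort the analysis assumes — a 304-patient
mixed ICU population with 31.57% in-hospital mortality in which thin APM
and high APACHE scores independently raise death odds. Defaults (all in
`data/paper_default.yaml`):

| component | default | rationale |
|---|---|---|
| APM thickness | truncated normal, mean 15.0, SD 4.0 mm on [6, 21], integer mm | unique (mean, SD) region whose integer median/quartiles are exactly 15 (12–17) under the clip |
| APACHE II | shifted gamma matched to median 15, IQR (12, 20), clip [0, 71] | right-skewed family; quantile function solved once per target triple |
| APACHE III | shifted gamma, median 47, IQR (33, 66), clip [0, 299]; Gaussian copula with APACHE II, Spearman ρ = 0.8 | both scores measured on the same patients; no joint law is published |
| outcome | logit P(death) = β₀ + β_M·(15 − t)₊ + β_A·APACHE II | hinge coding matches the scoring rule the pipeline must rediscover; a linear per-mm option exists |
| GCS points | round(0.33·APACHE II + N(0, 1.5)), clipped to [0, 12] and to the total | GCS is a major driver of APACHE II; remaining points split over 11 physiology columns so control fits can decompose the total |
| covariates | age N(54.75, 18.28²) ≥ 16; 61.5% male; albumin N(3.19, 0.72²); subtype 9.2/60.9/29.9% | printed overall demographics |

The intercept β₀ is never set by hand: `calibrate_intercept` bisects it on
a pilot draw (≥ 200 000) until expected mortality is within 0.1 percentage
points of the target; `resolve_intercept` freezes the value when many
replicate cohorts are needed.

The conditional slopes cannot be read off published tables, which report
*univariate* odds ratios: a univariate fit of a hinge-generated cohort is
attenuated by the omitted severity term. `calibrate_generator` therefore
calibrates the conditional coefficients by fixed-point iteration on pilot
draws until the *observable* quantities match their printed values: the
univariate per-point APACHE II OR (1.20), and — for the hinge default —
the thickness at which the fitted death-probability curve crosses 0.5
(10 mm, the categorisation anchor); the linear variant instead targets the
univariate per-mm APM OR (0.623). The frozen results (pilot n = 400 000,
seed 20180603, 6–8 rounds) are β_M = 0.4032, β_A = 0.2113, and
β_M = 0.6456 for the linear variant; the routine ships and a test verifies
it contracts toward its target. A consequence worth noting: with these
values the multivariable per-mm APM coefficient (≈ −0.26, the hinge slope
halved by linear projection about the median) lands close to the per-point
GCS coefficient (≈ +0.23), so the GCS-style linear rule emerges from the
derivation pipeline rather than being wired in.

What the generator does **not** emulate: real 24-hour physiologic time
series (the physiology *point* columns are a multinomial decomposition of
the total, not scored raw values — raw-panel scoring is exercised by
`generate_physiology_fixtures`, which builds random panels spanning every
table interval with a brute-force oracle score); correlation between APM
and APACHE scores (independence is assumed, so the composite's added value
reflects a genuinely independent signal — real thin patients may also be
sicker); admission time series, length of stay, readmission. Passing tests
show the pipeline's estimators and derivations behave correctly under the
assumed data-generating process, not that the composite scores improve
prediction in any real ICU.

## Problem sizes and numerical choices

Tests and the acceptance script scale simulations to what the estimators
need: exact identities at n = 1; calibration checks on one 100 000-patient
cohort; odds-ratio recovery at n = 50 000 (assessed within 3 standard
errors of the fit); the derivation identity (anchor 15, cutpoints (10, 15))
on a 10 000-patient cohort, where the cutpoint choice is stable; the
added-value check over 200 replicate cohorts of n = 304, the study's own
size. Logistic convergence uses Newton steps to tolerance 1e-10 (max 100
iterations); the gamma quantile solver requires residuals < 1e-6 on the
three target quantiles; bisections run on fixed brackets ([−20, 20] for the
intercept) and error if the target is not bracketed.

## Known limitations

* The categorical weights derived under the calibrated synthetic effect
  sizes are ≈ (7, 2, 0), not (40, 7, 0): the printed large ORs are not
  reproducible from the printed group counts either, which is why the
  default weights are shipped as a constant.
* At n = 304 the coefficient-closeness decision is unstable (the GCS
  coefficient's standard error is large); derivation at that scale should
  be interpreted as exploratory, exactly as the reported side-by-side
  diagnostics suggest.
* The APACHE II engine follows one fixed transcription of the score sheet;
  oxygenation uses the FiO2 ≥ 0.5 branch per reading and the serum-HCO3
  alternative to arterial pH is not implemented.
* Wald (not profile-likelihood) intervals throughout, matching the
  conventional SPSS-style output the derivation mirrors.
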