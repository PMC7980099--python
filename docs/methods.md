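# Methods

## Scoring model

The triage engine implements a two-part prognostic score computed per
patient-day.

**Short-term prognosis.** The daily SOFA score (six organ systems —
respiration, coagulation, liver, cardiovascular, CNS, renal — each graded
0–4, total 0–24) is computed from raw physiology by `csctriage.sofa` using
the 1996 consensus cut-points, stored in an editable YAML table
(`data/sofa_cutpoints.yaml`) so that SOFA dialects can be swapped without
code changes. Conventions that the consensus definition leaves implicit:

* respiratory subscores 3–4 additionally require ventilatory support
  (invasive or noninvasive); without support the subscore is capped at 2;
* the renal subscore is the worse of the creatinine-based and
  urine-output-based values when both are present;
* any vasopressor category other than "none" dominates the MAP criterion;
* a component whose inputs are all absent scores 0 — totals stay
  conservative rather than assuming worst-case — and the number of
  missing components is returned (`n_missing_components`) so callers can
  filter incomplete days. Upstream tables may instead supply a
  precomputed `sofa_score` column (mirroring an EHR auto-calculation),
  which bypasses this module entirely.

**Banding and points.** SOFA scores are banded into SOFA points
(<6 → 1, 6–8 → 2, 9–11 → 3, ≥12 → 4). Comorbidity points are 4 for any
1-year-survival-reducing condition, else 2 for any 5-year-reducing
condition, else 0 — one allotment for the most severe tier present, never
a sum. The default catalog (`data/comorbidities.yaml`) holds the
institutional policy's condition lists: 6 five-year and 9 one-year
conditions. Priority score = SOFA points + comorbidity points ∈ [1, 8].

**Groups and cut-points.** The policy consolidates scores into three
priority groups but does not print the cut-points. We default to the
unique contiguous three-way split consistent with the published
group-level comorbidity distribution (no 1-year-comorbidity patient in
group 1, which forces the group-1/2 boundary below 5; 5-year
comorbidities present in group 1, which forces it at or above 3):
1–3 → group 1, 4–5 → group 2, 6–8 → group 3. The mapping is a
configuration knob (`group_map` in the YAML config), not a constant. The
SOFA-points-only comparator grouping merges points 3 and 4 into group 3.

**Tiebreak cascade and allocation.** Within-group ties are broken
lexicographically: absence of a comorbidity known to affect short-term
recovery, younger age, provision of an essential health-care function,
lower raw priority score, then lottery. The policy does not enumerate the
short-term-recovery conditions, so that criterion is a per-patient boolean
supplied by the caller (or the generator); essential-function defaults to
false when absent. The allocation simulator (`allocate`) ranks a
cohort-day by this cascade and resolves residual ties by a uniform
lottery driven by a caller-supplied integer seed, making simulated
allocations auditable and reproducible. A weighted lottery was considered
and rejected: nothing in the policy suggests weights.

## Equity audit

Analysis is at the patient level. After dropping patient-days without a
SOFA score and patients without comorbidity data (each removal counted in
an exclusion log), every patient contributes the maximum and minimum of
their daily priority score, priority group, SOFA score and SOFA points —
eight outcomes.

Each outcome is regressed on race and ethnicity jointly (each is a
potential confounder for the other) plus sex, preferred language,
zip-code median-income band, primary insurer, age (continuous),
COVID-unit admission and hospital, in a Poisson GLM with log link.
Associations are reported as IRRs with Wald 95% CIs; two-tailed α = .05
and no multiplicity adjustment. Reference levels: White, Non-Hispanic,
Male, English, <$25k, Medicare/Medicaid, tertiary hospital.

* **Primary analysis** is complete-case: a patient is dropped if any
  model covariate is Unknown/missing.
* **Sensitivity 1** keeps every patient and retains Unknown as an
  explicit level of each categorical covariate.
* **Sensitivity 2** refits without the socioeconomic covariates (income
  band, insurer), which may themselves lie on the pathway between race
  and scoring.
* No offset term: each patient contributes one outcome, and days of data
  are not an exposure.
* Tiebreaker factors are deliberately excluded from the audit — the audit
  evaluates the score, not the downstream tie resolution.

**Standard errors.** The library default is model-based Wald SEs; a
sandwich (HC0) option is exposed because triage scores 1–8 are bounded
scores, not counts, so the Poisson variance assumption need not hold —
the usual modified-Poisson argument. The simulation-calibration tests use
the sandwich option for exactly that reason; both flavours leave point
estimates untouched (verified by test).

**Descriptives.** Characteristics are compared across priority groups
with Pearson χ² (no continuity correction, r×c tables, Unknown rows
retained — the choice under which the test statistics reproduce the
published group-comparison p-values) for categorical rows and
Kruskal-Wallis for continuous rows, plus a group-3-vs-1 column.
Degenerate tables (an all-zero row or column) are flagged, not raised.

**Reprioritization.** Per patient, the 3-level SOFA-points-only group is
compared with the full priority group at the chosen extremum; "higher"
means the full-algorithm group index is strictly smaller (better
priority). Fractions of higher/lower/unchanged are reported overall and
per race and ethnicity level; the three fractions sum to 1 by
construction.

## Synthetic cohort generator

The generator emulates the structure of the two-hospital study
population: n = 1127 patients; race marginals 63.1/28.7/0.7/2.8/4.8%
(White/Black/Asian/Multiracial/Unknown); ethnicity 42.6/54.2/3.2%
(Non-Hispanic/Hispanic/Unknown); 53.9% men; language, income-band and
insurer marginals from the published baseline table; 61.2% COVID-unit
admission; 59.9% tertiary hospital; comorbidity-tier prevalences 36.2%
(5-year) and 19.3% (1-year), drawn independently; age ≈ N(62.7, 16.3²)
truncated to [18, 100], matching the published median and IQR.

* **Days of data** follow 1 + NegBin(size 0.7, mean 4.5): an
  overdispersed law whose quartiles reproduce the published median 3 and
  IQR 2–7 exactly (parameters found by grid search on the quartiles).
* **SOFA trajectories** follow a latent AR(1) severity path
  (baseline N(2.5, 2.5²), ρ = 0.7, innovation SD 1.5), rounded and
  clipped to [0, 24] — the minimal structure giving day-to-day
  correlation; the study reports no dynamics. Baseline parameters were
  chosen so that most patient-days band to 1 SOFA point and the maximum
  priority group distribution is dominated by group 1, qualitatively
  matching the published distribution; they are not fit to it.
* **Disparity injection**: `disparity_log_irr` (e.g. `{"race:Black":
  0.2}`) scales latent severity multiplicatively per demographic level;
  the default (all zero, demographics independent of comorbidities and
  severity) is the null. Coupling knobs, not defaults, are how a
  comorbidity-burden disparity is simulated.
* **Poisson emission mode**: for parameter-recovery studies the
  generator can draw each day's SOFA score from
  Poisson(mean × exp(effect)) with one day per patient
  (`recovery_profile()`). Under that emission the audit's Poisson GLM on
  the max-SOFA-score outcome is correctly specified, so the injected
  log-IRR is the estimand and exp(0.2) is recoverable exactly. Under the
  banded priority-score outcome a severity shift has no closed-form IRR
  (banding attenuates), which is why recovery is assessed on the outcome
  where the estimand is defined.
* All randomness flows from one seed through splittable per-patient
  streams (`numpy.random.SeedSequence.spawn`), so regenerating a subset
  of patients is stable and a fixed seed is bit-reproducible.
* Missingness knobs (`missing_sofa_day_rate`,
  `missing_comorbidity_rate`) default to 0 so the default cohort matches
  the printed post-exclusion size and marginals; set them to exercise the
  exclusion filters.
* Tiebreak flags: short-term-recovery comorbidity prevalence 0.2,
  essential-function 0.05 — plausible hospital-population values chosen
  once; the study reports neither.

What the generator does **not** emulate: the real joint distribution of
covariates (race × income × insurer are drawn independently), physiologic
plausibility of SOFA component values, disease progression, or
inter-hospital case-mix differences. Passing tests therefore demonstrate
correctness of the scoring and audit machinery and calibration under the
stated generating model — not properties of any real population.

## Numerical and design choices

* χ² without continuity correction; Unknown rows retained (both required
  to reproduce the published descriptive p-values, verified in tests).
* Collinear design columns raise an error naming the columns; a
  categorical level emptied by complete-case filtering is dropped with a
  warning.
* Constant outcomes are handled by the GLM (all IRRs 1), empty cohorts
  raise.
* Report formatting mirrors journal style: IRR to 2 decimals with the CI
  as `1.00 (0.89-1.12)`; p-values as `<.001`, `.003`, `.94`.
* CSV missing values are empty fields, surfaced as the uniform `Unknown`
  level; the literal insurer level `None` is preserved on read. An empty
  `comorbidities` field means data unavailable (patient excluded); the
  string `none` means assessed with none found.
* CLI exit codes: 0 success, 2 validation failure, 3 model-fit failure;
  every run appends a structured log line (command, seed, config hash).

## Problem sizes in the test suite

The calibration tests run 200 null cohorts at n = 1127 (type-I error of
the Black-vs-White CI checked against the exact binomial 95% interval
around 0.05) and 100 recovery replicates at n = 5000; the
marginal-matching test uses one draw at n = 50,000 with 1% tolerance.
These sizes give Monte-Carlo error comfortably below the tolerances
tested while keeping the full suite under a few minutes on one CPU.

## Known limitations

* The audit is associational; no causal or mediation claims.
* Poisson IRRs on a bounded 1–8 score are a modelling convention
  inherited from the audited design; the sandwich-SE option mitigates,
  but does not remove, the variance misspecification.
* The SOFA engine targets the adult consensus definition only (no
  pediatric SOFA, no qSOFA, no validation against outcomes).
* Reassessment/withdrawal over time and triage-team overrides are out of
  scope; the allocation simulator ranks a single cohort-day.
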