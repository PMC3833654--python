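# Methods

## The analysis chain

`homacut` models the standard workflow of a cross-sectional pediatric
metabolic survey. Per subject, insulin resistance is summarised by the
homeostasis-model index HOMA-IR = insulin (mU/L) × glucose (mmol/L) / 22.5,
valid for fasting measurements; it is a static surrogate for
clamp-measured insulin sensitivity and is right-skewed, so it is
log-transformed wherever a symmetric summary is needed.

Metabolic syndrome follows a modified ATP III pediatric definition:
a subject is classified MS when at least three of five components are
present —

| component | rule | provenance |
|---|---|---|
| central obesity | WC ≥ p90 of the (age band, sex) stratum | cohort-derived |
| elevated BP | SBP ≥ p95 **or** DBP ≥ p95 of the (age band, sex, height band) stratum | cohort-derived |
| hypertriglyceridemia | TG ≥ 1.24 mmol/L | fixed |
| low HDL-C | HDL ≤ 1.03 mmol/L | fixed |
| impaired fasting glucose | glucose ≥ 5.6 mmol/L | fixed |

All comparisons are inclusive. The fixed cuts correspond to outer
percentiles of a healthy reference population in the definition this
package adapts; they are attached verbatim rather than re-derived, so
they remain comparable across cohorts.

Two cut-off families are then derived for HOMA-IR:

* **Normative**: the 95th percentile of HOMA-IR in the *reference
  population* — subjects of normal weight (BMI between the 5th and 85th
  age/sex percentile) with zero MS components — overall and within sex,
  age (6–9, ≥10, 10–15, ≥16) and Tanner (I, ≥II, II–IV, V) strata. The
  age and Tanner strata deliberately overlap; row n's are not meant to
  sum to the total.
* **Diagnostic**: the empirical ROC of HOMA-IR against MS status, with
  the optimum chosen by maximum Youden index J = sens + spec − 1 or
  minimum squared distance (1 − sens)² + (1 − spec)² to the
  perfect-classification corner. The distance is minimised on the
  squared scale; the square root changes no argmin.

Association is quantified by quintile odds ratios: HOMA-IR is binned
into cohort quintiles and each outcome (MS and the five components) is
regressed on quintile indicators (quintile 1 referent) plus age, sex,
and Tanner stage, by maximum-likelihood logistic regression. Prevalence
of insulin resistance (HOMA-IR strictly above a labelled cut-off) is
tabulated by MS/component group and weight status, with Pearson χ²
comparisons across weight-status groups.

## Numerical conventions

* **Quantiles.** One convention everywhere: linear interpolation of the
  order statistics at rank h = 1 + (n − 1)p (numpy's `"linear"`
  method). Published survey analyses rarely state their quantile rule;
  fixing a single rule makes every threshold in the package exactly
  reproducible and self-consistent (a reference applied to its own p95
  leaves ~5% strictly above it, up to interpolation granularity).
* **Positive-call rule.** Strictly-greater (`score > cutoff`), matching
  the clinical reading of "HOMA-IR > 3.0"; an inclusive rule is
  available behind a flag on `build_roc` / `prevalence_of_ir`.
* **ROC construction.** Candidate cut-offs are the distinct observed
  scores plus one sentinel below the minimum, so the curve always
  reaches (sens 1, spec 0) and (sens 0, spec 1). The trapezoidal AUC
  over this candidate set equals the tie-corrected Mann–Whitney
  concordance probability exactly, which the tests verify against a
  brute-force pairwise oracle.
* **Tie-breaking.** At equal Youden index the smaller squared distance
  wins, and vice versa; remaining ties go to the smaller cut-off. Output
  is therefore deterministic.
* **Logistic fits.** Newton's method to parameter tolerance 1e−8
  (≤ 100 iterations), Wald 95% intervals and p-values (survey CIs of
  the form `24.87–130.92` are symmetric on the log scale, i.e. Wald).
  Saturated quintile-only fits reproduce the closed-form ad/bc odds
  ratios; the hand-written Woolf-interval `crude_or` is kept as the
  independent oracle. Perfect separation or non-convergence yields
  flagged rows with unbounded intervals, not an exception. Tanner stage
  enters as a numeric ordinal (survey tables report mean Tanner stage,
  implying numeric treatment); indicator coding can be passed via the
  covariate frame if wanted.
* **Weight status.** Bands are closed on the left: percentile in
  [5, 85] normal, (85, 95] overweight, > 95 obese. Below the 5th
  percentile is flagged `underweight` and excluded from the reference
  population rather than silently counted normal — the handling of such
  subjects is otherwise undefined in the definitions this package
  follows. The growth reference is injected (empirical samples,
  p05/p85/p95 curves, or LMS triplets); national growth-chart data are
  external and deliberately not bundled. The pipeline derives its
  reference from the analysis cohort itself.
* **Component threshold strata.** One-year age bands by default
  (configurable width); blood pressure uses height tertiles within each
  (age band, sex) stratum (`n_height_bands=1` disables height
  adjustment). Whether published pediatric BP percentiles use height
  bands or a height regression is typically unstated; bands are the
  documented choice here. A stratum below the minimum size (default 20)
  raises an error naming the stratum.
* **Quintiles.** Interior bounds at p ∈ {0.2, 0.4, 0.6, 0.8}; subject
  in quintile k per the half-open intervals (b_{k−1}, b_k]. Massive ties
  that collapse bounds raise a flagged error. Externally supplied bounds
  (e.g. published quintile limits) can be passed verbatim.
* **GEE note.** Survey analyses of this kind sometimes cite
  logistic-regression GEE models without identifying the clustering
  unit. This package fits an independence-working-model (ordinary ML)
  logistic regression; point estimates coincide under independence, and
  no clustering variable exists in the synthetic design.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not any particular real dataset. Per subject: sex ~ Bernoulli(0.524
male); age ~ Uniform(6, 18) years; Tanner stage drawn from a per-age
categorical table (stage I dominant below 10, II–IV across 10–15, V
from 16); a single latent standard-normal factor Z ("adiposity /
insulin resistance") loads on every metabolic variable; residual noise
is independent normal (log-normal for TG and insulin; glucose truncated
at 2.5 mmol/L; physiological floors elsewhere). Height follows an
age-sex growth line and weight is back-computed from generated BMI, so
BMI ≡ weight/height² exactly.

Key default parameters (units; value; rationale):

* `n_subjects` 3200 and `male_fraction` 0.524 — the survey scale the
  package targets (~3200 children, slight male excess).
* `insulin_stage_geomeans` (mU/L): I 4.4, II–IV 7.4, V 6.5 — the
  pubertal rise and partial late-pubertal recovery of fasting insulin;
  with glucose ~5.05 mmol/L these put reference-population HOMA-IR
  means near 0.93 (Tanner I), ~1.6 (II–IV) and ~1.4 (V).
* `glucose_mean_sd` (5.05, 0.30) mmol/L plus latent loading 0.48 —
  yields an impaired-fasting-glucose rate around 16% in the risk-coupled
  cohort.
* latent loadings (per SD of Z): BMI 2.6 kg/m², WC 6.5 cm, fat% 5.0,
  SBP 9.5 / DBP 7.5 mmHg, log-TG 0.60, HDL −0.30 mmol/L, log-insulin
  0.36, glucose 0.48 mmol/L — chosen by simulation so that, under the
  package's own classification with cohort-derived thresholds, MS
  prevalence lands near 13%, the reference-population HOMA-IR p95 near
  3.0, the HOMA-IR-vs-MS AUC near 0.81, and the top-quintile MS odds
  ratio in the several-tens range. These defaults are the package's
  study conditions and are exercised, not tuned, by the tests.
* `component_noise_sd` — residual scatter per variable; insulin's
  log-noise 0.55 dominates its total log-SD (~0.66), reproducing the
  strong right skew of pediatric HOMA-IR (reference p95 ≈ 2.3 × mean).

What the generator does **not** emulate: real growth-chart geometry
(weight status is judged against the cohort's own BMI percentiles, so
~15% are overweight-or-obese by construction, unlike risk-enriched real
samples), measurement error and assay non-standardisation, school-level
clustering, non-uniform age pyramids, and any secular trend. Passing
tests therefore show the *machinery* is correct and the qualitative
patterns (monotone HOMA-IR across component counts, steep OR gradients,
higher IR prevalence in obesity) follow from the assumed structure —
they do not validate the defaults against any real population, and
absolute numbers (e.g. the ROC cut-off ~1.8 versus published values
above 2) shift with the latent-factor strength and skew.

## Problem sizes used in the checks

The test suite and the acceptance script run the full pipeline at the
survey scale (n = 3203) and replicate-based pattern checks at 20 seeds;
oracle-equivalence checks (AUC vs pairwise concordance, logistic vs
closed form) run on hundreds of small random instances (n ≤ 50 and
five-quintile count tables). Parameter recovery uses two log-normal
classes of 1000 subjects each, whose equal-log-variance density
crossing exp((μ₀ + μ₁)/2) is known in closed form; the empirical
Youden argmax converges at a cube-root rate, so recovery is assessed on
the error aggregated over 20 replicates.

## Known limitations

* The empirical growth reference cannot flag obesity prevalence
  differing from its own tail mass; plug in an external p05/p85/p95 or
  LMS table to classify against a fixed standard.
* Reference-percentile strata with very small n (e.g. Tanner V in a
  young cohort) produce noisy p95 values; rows carry n so consumers can
  judge.
* No confidence intervals for AUC or cut-points; no multiple-testing
  adjustment across the per-component OR tables.
* The IDF pediatric MS definition (central obesity mandatory) is out of
  scope.
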