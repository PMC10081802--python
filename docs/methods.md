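# Methods

This note documents the statistical model, the estimators, the synthetic
cohort generator, the numerical choices, and the limits of what the test
suite demonstrates.

## Effect size and estimation

The discriminative ability ("cross-sectional sensitivity") of an instrument
between two patient arms is the Mann-Whitney functional
θ = P(X > Y) + ½P(X = Y) on oriented scores (higher = better). Symptom
scales are reflected by x ↦ max + min − x before analysis, so θ > 0.5
always reads "first arm better". θ is rank-based, hence invariant under
strictly monotone transforms of both arms, and equals the trapezoidal
ROC area.

**Estimator.** Midranks over the combined sample:
θ̂ = (R₁ − n₁(n₁+1)/2)/(n₁n₂), which counts wins plus half-ties. A
brute-force pair-counting path (`mw_effect_bruteforce`) is retained and the
two are held equal to 1e-12 on randomized tied instances in the tests.

**Variance.** The placement-value estimator: with V10ᵢ = P̂(xᵢ > Y) and
V01ⱼ = P̂(X > yⱼ), var(θ̂) = S10/n₁ + S01/n₂ (sample variances of the
placements). This is consistent under ties and algebraically identical to
the grouped delete-one jackknife, which the tests exploit as an oracle.
Degenerate cases are flagged: zero variance under complete separation, and
undefined variance when an arm has fewer than two observations.

**Intervals.** Wald θ̂ ± z·SE on the identity scale, clipped to [0, 1]
(matches forest-plot bounds); a logit-scale alternative is available by
argument. Simulated coverage at θ = 0.71, n = 50/arm is 95% ± 2%.

**Effect bands.** small 0.36 ≤ θ ≤ 0.64; large θ ≤ 0.29 or θ ≥ 0.71;
medium in between. Boundary membership is inclusive exactly as printed
(0.36/0.64 are small; 0.29/0.71 are large) and tested at the boundaries.

## Wei-Lachin pooling

For K outcomes measured on the same subjects, the cross-outcome covariance
of the θ̂s is built from the same placements: Σₖₗ = S10ₖₗ/n₁ + S01ₖₗ/n₂,
whose diagonal reproduces the univariate variances. The pooled estimate is
θ̄ = wᵀθ̂ with var = wᵀΣw and z = (θ̄ − 0.5)/√var referred to the standard
normal, two-sided. Weights are equal by default (the unweighted Wei-Lachin
combination); inverse-variance weights are available by configuration.
Pooled estimates use complete-case subjects across the K outcomes, while
univariate estimates use all data available per instrument — mirroring
per-instrument "data as available" analyses alongside a joint pooled
figure. Under a simulated global null with K = 8 correlated outcomes the
pooled test's rejection rate matches the adjusted alpha within Monte-Carlo
error.

**Multiplicity.** Bonferroni families with fixed adjusted alphas:
instrument-level design A 0.00045, design-B PROM comparisons 0.005,
group-level comparisons 0.0001; a generic base-alpha/m helper covers other
families. Significance is reported per row, but the sensitivity summaries
count comparisons by effect class alone by default
(`count_rule="effect_only"`); requiring significance as well is a
configuration switch, since the published summaries do not state which rule
they used.

## Designs, feasibility, summaries

Design A enumerates eight factor contrasts (six factors; the three-level
care pathway contributes its three pairwise contrasts) within each of the
four GCS+CT TBI-severity strata, on all instruments including the merged
GOSE/-Q. Design B enumerates the three recovery contrasts (good 7–8 vs
moderate 5–6 vs severe 2/3–4; death excluded, as every PROM is a
self-report) within 17 patient-group contexts — the six factors' levels
plus the four severity strata — on the PROMs, with a pooled Wei-Lachin row
per comparison.

A comparison is *feasible* when both arms have at least `min_arm_n`
members (default 10; the source analyses report infeasible comparisons
without stating their threshold, so this is configurable and logged per
comparison). Sensitivity per instrument × time point is the percent of
feasible comparisons with at least a medium class; the across-time average
is the unweighted mean of the per-time percentages; percentages are
reported rounded to whole percent in the text summary with raw fractions
retained. Ranking is competition-style (ties share a rank) with top-3
flags. Recommendation labels take the modal effect class over a context's
comparisons — large → strongly recommended, medium → recommended, small →
little information gain — with modal ties resolved toward the weaker
label, a deliberately conservative reading of "predominantly".

**Missing-data modes.** `as_available` uses every record with the outcome
present; `completers` first restricts the cohort to subjects with at least
one non-missing outcome at all three time points and then runs the
identical analysis, so completers output equals the as-available output on
the restricted cohort by construction (and by test).

## Instrument scoring

Sum scales (GAD-7 0–21, PHQ-9 0–27, PCL-5 0–80, RPQ 0–64) prorate the
observed item mean when at most a third of items are missing (default
`max_missing_items = 1/3`, configurable; the source does not state its
proration rule). The QOLIBRI/-OS percent transform is the published linear
rescaling of the item mean from [1, 5] to [0, 100]. RPQ totals are a plain
sum of the 16 ratings, matching the printed 0–64 range; the instrument's
historic "discard ratings of 1" dialect is not applied. SF-36v2/SF-12v2
component T-scores are consumed as provided columns — the proprietary
norm-based coefficient sets are not reimplemented — with missing SF-12
items optionally backfilled from their SF-36 counterparts
(`fill_sf12_from_sf36`), never overwriting reported values.

Clinical impairment cut-offs: GAD-7 ≥ 10, PHQ-9 ≥ 10, PCL-5 ≥ 33,
RPQ ≥ 12, QOLIBRI < 60, QOLIBRI-OS < 52, PCS/MCS < 40 (study rule,
50 − 1 SD; the US-norm 47 is available via `default_registry(sf_cutoff=47)`),
GOSE/-Q < 7. Boundary behaviour is tested at every cut-off.

**GOSE merging.** Sources are merged in priority order interview →
questionnaire → interviewer rating; the GOSE-Q/rater only ever substitutes
a missing interview. Levels 2 (vegetative) and 3 (lower severe disability)
collapse into one category, leaving 7 ordinal levels coded 1..7 with
labels 1, 2/3, 4, 5, 6, 7, 8.

## Synthetic cohort generator

The generator's purpose is to emulate the statistical structure the
analysis assumes, not to model TBI recovery mechanistically.

* **Joint law.** A Gaussian copula over K = 11 latent domains (GOSE + ten
  PROM scores). Default correlations: 0.45 baseline, 0.85 within
  long/short form pairs, 0.6 within the mental-health cluster, 0.55–0.6
  between GOSE and the HRQOL domains, and 0.15 between every PCS and MCS
  pair — chosen so the *observed* Spearman PCS–MCS stays below 0.30 after
  group shifts add a little common variance, while other pairs sit at
  moderate-to-high values.
* **Marginals.** Monotone quantile maps from the health latent onto each
  discrete scale: beta-binomial shapes per instrument, calibrated
  analytically so marginal impairment prevalences fall in clinically
  reported bands (anxiety/depression/PTSD ≈ 8–13%, post-concussion
  symptoms ≈ 40%, TBI-specific HRQOL ≈ 23–27%); T-scores as 45 + 10·latent
  rounded to 0.1 and clipped to [0, 100] (≈ 31% below 40). The GOSE is an
  ordinal cut at fixed normal quantiles with merged-category masses
  (.02, .08, .08, .12, .13, .27, .30), putting incomplete recovery at 43%.
* **Group effects.** Latent location shifts per (factor, level), calibrated
  to MW targets via δ = √2·Φ⁻¹(θ) and mean-centered within each factor
  (weighted by level prevalence) so marginal distributions stay at the
  calibrated bands. Defaults make functional recovery the most
  group-separated domain, physical HRQOL most sensitive to injury-related
  factors, and the mental-health cluster most sensitive to premorbid
  psychological problems. Because θ is rank-invariant, a latent target
  transfers to the score scale exactly up to discretization ties; the gap
  shrinks with scale resolution (tested), so coarse scales (GOSE, GAD-7)
  realize somewhat smaller observed effects than T-scores.
* **Cohort composition.** ~65% male, ~25% aged 65+, ~70% at least
  secondary education, ~35% premorbid psychological problems, pathway
  25/30/45 ER/ADM/ICU, severity 36/36/8/20, ISS from a discretized
  gamma(2, 7) (~61% ≥ 10). Subjects carry a latent random effect linking
  the three assessment months (correlation 0.7) plus a small improvement
  trend (+0.15/+0.25 latent at 6/12 months); death (GOSE level 1) is
  absorbing and suppresses all self-reports.
* **Missingness.** MCAR per instrument × time (PROMs 20–30%, GOSE
  interview 16–20%, inside the reported 14–21% band). A GOSE-Q shadow
  agrees with the collapsed interview with probability 0.8, else moves one
  merged level (never into death); an interviewer rating is available for
  ~30% of records. After merging, GOSE missingness drops to a few percent.
  An MAR mechanism is deliberately not default: the source does not
  characterize its missingness mechanism.

**What passing tests do and do not show.** The generator demonstrates that
the pipeline recovers configured stochastic-ordering structure, calibrated
effect targets, prevalence bands and correlation patterns. It does not
establish anything about real registry data: covariates are drawn
independently (real severity, pathway and ISS are correlated), missingness
is MCAR, cross-time dependence is a single equicorrelated random effect,
and the marginal shapes are plausibility choices.

## Numerical and design choices

* Midrank ranks via `scipy.stats.rankdata`; placements via sorted-array
  `searchsorted`, so the whole analysis is O(n log n) per comparison.
* Ties in classification cannot occur at band boundaries by construction
  (bands are closed exactly as printed); ranking ties share the minimum
  rank; recommendation ties go to the weaker label.
* Zero-variance or singular pooled variance yields a flagged degenerate
  result with no p-value rather than an exception.
* Empty arms raise a typed `InfeasibleComparison`; the pipeline converts
  this into a flagged infeasible row with a reason string, never silent
  omission.
* Config objects are plain dataclasses; YAML loading validates field names
  and reports `block.field` paths. Missing values are empty CSV fields
  throughout — no numeric sentinels.
* Problem sizes in the test suite (cohorts of 400–4000 subjects, 200–2000
  Monte-Carlo replicates) were chosen so every statistical check sits at
  ≥ 3 sampling standard deviations from its threshold while the whole
  suite stays fast on one CPU.

## Known limitations

* No stratified (van Elteren-type) combination across sites and no exact
  permutation p-values (a configuration hook is reserved).
* The proprietary SF component-score coefficient sets are not
  reimplemented; T-scores are inputs. The generator's simplified
  45 + 10·latent transform exists only for simulation.
* The comparison inventory is configurable rather than hard-coded to any
  published count of feasible comparisons, because the published inventory
  is not enumerated item by item.
* Whether published percentage summaries additionally required
  significance is unknown; both counting rules are provided, effect-only
  is the default.
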