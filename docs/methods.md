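# Methods

`hospmort` implements and stress-tests three ways of counting 30-day mortality
as a hospital quality indicator for acute admissions (AMI, stroke, hip
fracture), with particular care for patients transferred between hospitals.

## Episodes of care

The unit of analysis is the *episode of care*: the chain of one patient's
hospital stays in which each admission begins at most 24 hours (boundary
inclusive) after the previous discharge. An episode spanning two or more
distinct hospitals is a *transferred* episode; a ≤24 h readmission to the same
hospital chains but does not make the episode "transferred". Record-level
exclusions are applied first — age below 18 years (AMI, stroke) or 65 years
(hip fracture), dead on arrival, non-acute admission, rehabilitation stays,
and records with missing mandatory fields — then only the first episode per
patient per calendar year is kept. The first-admission rule is applied to
chains rather than raw records so that a transfer stay is never orphaned from
its index admission. Hospitals need at least 20 retained admissions in every
study year; study years are the years of index admissions (a chained stay
beginning just after New Year must not create a spurious year). The volume
filter runs after the exclusions and before chaining; whether it should
precede or follow chaining is genuinely open, and the choice is surfaced as a
parameter rather than asserted.

Data-quality conventions: overlapping stays for one patient are a data error
resolved by truncating the earlier stay's end to the later stay's start
(preserves total in-hospital time; a warning is logged). Deaths carry dates,
not times, so death-during-stay is decided at date precision; a death dated on
a stay's discharge day counts as in-hospital for that stay, and a death dated
on a transfer day (discharge of one stay, admission of the next) is attributed
to the later stay.

## The three counting rules

All measures count all-cause deaths. With the index admission at time 0 and a
window of `W = 30` days:

* **W30D** — death within `W` days of the first day of the index admission, in
  or out of hospital. For a transfer chain the single outcome is attributed to
  every hospital `h` with weight

  `w_h = (in-hospital days at h, truncated at day W) / (total truncated in-hospital days)`,

  so weights sum to 1 per episode and no death is double-counted. Same-hospital
  stays pool. A 10-day stay followed by 15 days at a second hospital gives
  weights 10/25 and 15/25; if the second stay runs to day 31 the truncated
  weights are 10/30 and 20/30. A hospital whose entire stay falls beyond day
  `W` receives weight 0 and no observation.
* **S30D** — same outcome definition, restricted to episodes treated at a
  single hospital; transferred episodes are excluded entirely. Weight 1.
* **IH30D** — in-hospital deaths only, with the 30-day clock restarting at
  each hospital's own first admission in the chain: earlier hospitals count
  the patient as a survivor, and an out-of-hospital death counts nowhere.
  Weight 1.

Boundary conventions: a death whose date is exactly `W` days after the index
date counts as a death (the published worked example pins only day 31 as
"alive"; the day-30 side is our convention and is stated, not attributed).
Durations are fractional days from hour-resolution timestamps; with whole-day
inputs the worked fractions above are reproduced exactly.

Crude mortality per hospital is the weighted death proportion
`Σ w·y / Σ w`; the cohort summary tabulates deaths by interval (≤30, 31–90,
91–365 days, alive beyond one year), place of death within 30 days (during the
first admission / in a different hospital / out of hospital), and whether the
underlying or any contributing cause of death falls in the referral
condition's ICD code set (prefix match, ICD-9 and ICD-10 stems).

## Case-mix adjustment and hospital profiling

Per measure and condition, observations (one per hospital × episode, with the
W30D fractional weight) enter a logistic regression of the outcome on:

* age — B-spline basis, cubic by default with three interior knots at the
  25/50/75 age percentiles of the analysis table (the basis function absorbed
  by the intercept is dropped, so `degree + n_knots` columns). Degree and
  knots are configurable because the published analysis states B-splines
  without further detail;
* sex (indicator), disease stage (categorical; empty levels dropped with a
  warning);
* hospital — sum-to-zero (deviation) contrasts, so each coefficient is the
  hospital's log-odds deviation from the mean of all hospitals; the
  constrained J-th effect is recovered as minus the sum of the fitted J−1
  contrasts, with its standard error from the contrast covariance
  (`var = 1'V1`).

Estimation maximizes the weighted binomial log-likelihood
`Σ_i w_i [y_i log p_i + (1−y_i) log(1−p_i)]` by iteratively reweighted least
squares with step halving. Convergence: largest absolute score component
below 1e-8 or relative log-likelihood change below 1e-10, at most 100
iterations. The covariance is the inverse of the weighted Fisher information.
Weights that are multiples of `1/K` reproduce the unweighted fit on the
`K`-fold replicated pseudo-dataset exactly (point estimates; covariances
differ by the factor `K`), which is the oracle used in tests; estimates are
invariant to rescaling all weights.

Hospitals with zero (or all) weighted events would quasi-separate the
deviation contrasts, so such fits — and any fit that fails to converge with a
linear predictor exceeding 15 in absolute value — use a Firth-type penalized
refit (Jeffreys-prior score adjustment generalized to observation weights,
`score += X'[h(½ − p)]` with `h` the hat diagonal of the weighted
information). This keeps every hospital classifiable; `penalized = true` is
surfaced in the output.

Profiling: `Z = beta / se` (a Wald statistic; the published analysis says only
"Z-values"), outlier categories low / medium / high with strict inequalities
against the normal tail quantiles (`Z < Φ⁻¹(0.05) = −1.6449` is low,
`Z > Φ⁻¹(0.95)` is high, a Z exactly at a threshold is medium), and ranks with
1 = lowest mortality, average ranks on ties. Discrimination is the weighted
concordance over (death, survivor) pairs with pair weight `w_i w_j` and ties
counting ½, computed by a sort-and-accumulate pass; it is undefined (None,
with a warning) when either outcome class is empty.

## Measure comparison

S30D and IH30D are each compared against W30D on the common hospital set:

* Spearman rank correlation = Pearson correlation of the tie-averaged rank
  vectors (undefined for a constant vector);
* per-hospital rank shifts `d = rank_other − rank_ref` bucketed as none
  (`|d| = 0`), minor (`0 < |d| ≤ 5`), moderate (`5 < |d| ≤ 10`), major
  (`|d| > 10`), with direction (negative `d` = toward lower mortality). The
  half-open band convention resolves fractional tie-averaged ranks, which the
  integer phrasing of the published categories leaves open;
* the 3×3 outlier cross-tab (rows = reference status) with change fraction
  `1 − trace/total`;
* Spearman correlation between ranks and hospital mean length of stay;
* one-way fixed-effects ANOVA of `|d|` across hospital size categories
  (degenerate groups → undefined; zero between- and within-variance →
  `F = 0, p = 1`);
* an exact test of change/no-change in outlier status by category: full
  enumeration of 2×C tables with the observed margins under the multivariate
  hypergeometric null, summing probabilities not exceeding the observed
  table's (≤ 60 hospitals keep this cheap). A zero margin gives `p = 1` by
  convention.

Both adjusted (deviation coefficients) and unadjusted (crude proportions)
rankings are produced and labelled.

## The synthetic registry

Real national registry extracts are not redistributable, so the generator
emulates their structure with known ground truth. Per condition it draws
hospitals in three size categories with latent log-odds deviations
`Normal(0, σ_H²)` centered to zero mean within category, per-hospital volumes
around category means with mean-preserving lognormal jitter, admission times
uniform over the study years at 1-hour resolution, case mix (truncated-normal
age, Bernoulli sex, categorical stage), lognormal lengths of stay, and
transfer chains (second and rarely third stays at destinations drawn from a
category-to-category transition matrix, inter-stay gaps 1–20 h).

The death indicator is Bernoulli with
`logit p = b0 + Σ_h w_h θ_h + β_age (age − 75) + β_sex·female + β_stage`,
where `w_h` are the planned stays' truncated time fractions — i.e. the
estimand of W30D, which is what makes parameter recovery a meaningful
end-to-end test. The intercept `b0` is calibrated by root finding on the
realized covariate draw so the marginal 30-day mortality matches the
configured target. Deaths within 30 days are placed in hospital (a stay
chosen with probability proportional to its in-window time, the episode
truncated at death) or out of hospital (after the last discharge, uniform in
the remaining window) according to the configured out-of-hospital share; a
configured fraction of 30-day survivors dies in the 31–90 and 91–365 day
intervals, out of hospital. Cause-of-death codes match the referral code set
with a configured probability (per interval). The realized out-of-hospital
share runs one to three points below the configured one: deaths drawn shortly
after discharge can fall on the discharge date and then classify as
in-hospital under the date-precision rule, and episodes still in hospital at
day 30 cannot die out of hospital.

Default parameter values are the published national margins per condition:
hospital counts (34/16/5, 38/16/5, 39/15/4 small/large/university), 5 study
years, 30-day mortality 19.1 / 17.6 / 7.8%, transfer rates 5.1 / 4.8 / 6.6%,
female shares 38.0 / 49.8 / 74.2%, mean stay 8.6 / 14.0 / 11.8 days (with
shorter first and longer second stays for transfers), out-of-hospital shares
of 30-day deaths 11.1 / 16.5 / 51.0%, cause-match shares 73.8 / 89.6 / 75.9%,
and category-to-category transfer matrices row-normalized from the published
transfer counts. Per-hospital patient volumes are back-computed as published
admissions per category divided by hospitals, years and (1 + transfer rate),
because a transferred patient appears in two hospitals' admission counts.
Where no value is published the default is a single considered choice: true
hospital-effect SD 0.2 log-odds (≈ ±20% odds for a typical hospital;
recovery studies use 0.3 as their stated condition), age means/SDs chosen to
match the published >75-year shares, stage distributions and log-odds
(free parameters, not calibrated claims), and zero rates for dead-on-arrival
/ elective / rehabilitation records since the emulated margins describe the
post-exclusion cohort (the rates are config knobs used to exercise the
exclusion rules).

What the generator does **not** emulate — and hence what passing tests do not
show about real data: diagnostic coding error and hospital-specific coding
practice, seasonal or weekday admission patterns, competing risks beyond the
single death outcome, dependence of transfer probability on severity or on
the index hospital's own quality, readmissions beyond the transfer window,
and any real hospital's identity or rank. One latent stream seeds every draw,
so identical configurations give byte-identical tables.

## Problem sizes and runtimes

Validation studies are sized to be decisive yet quick: null calibration uses
200 one-year replicates of a 15-hospital registry at the AMI per-hospital
volumes (~2 450 episodes each; each tail should flag about 5% of hospitals,
and the observed means lie inside 3–7%, the high tail running slightly above
the low one because more deaths mean smaller standard errors); parameter
recovery uses the
full 55-hospital, 5-year AMI registry (~50 000 episodes, truth–estimate
correlation above 0.8, observed ≈ 0.9). The analysis scripts run the three
full-size registries end to end in a few minutes on one CPU.

## Known limitations

Fixed-effects profiling with normal-tail cut-offs is deliberately faithful to
the published procedure: no hierarchical shrinkage, no over-dispersion
correction, no multiplicity adjustment across hospitals, and no rankability
or league-table uncertainty statistics. Condition membership is taken from
the condition column (no ICD extraction from coded records). The Wald Z is
slightly conservative for small, low-event hospitals, which is visible as a
mildly asymmetric null flag rate at small per-hospital volumes. Firth-penalized
effects for zero-event hospitals are finite but shrunken; their Z-values
should be read qualitatively.
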