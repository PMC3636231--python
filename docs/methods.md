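# Methods

`weightflow` implements the analysis chain used to study the relationship
between website engagement and self-reported weight change in free,
self-directed online weight-loss programs: screening weight entries for
data-entry errors, constructing an analyzable cohort, coding engagement
predictors, and regressing weight-change outcomes on them.  Because no
member-level dataset of this kind is publicly deposited, a synthetic-data
generator with ground truth is a first-class component: it defines the
conditions under which the pipeline's behaviour is tested, including exact
knowledge of which entries are corrupted and what the true
engagement-weight effects are.

## Screening model

Baseline exclusions remove members whose roster attributes are physically
implausible: age > 100 years, height > 120 in, or a baseline weight
outside 100-800 lb *with no follow-up entries* (an extreme first weight
followed by later entries is left to the entry-level filters, which can
see the trajectory context).

Four automated filters then flag suspect entries.  All filters operate on
day-collapsed entries (multiple same-day weights collapse to the last of
the day), so "entry days" is the unit throughout and inter-entry day gaps
are never zero.

* **F1 (quadratic residual)** fits weight = a + b·t + c·t² by OLS per
  member and flags entries whose residual exceeds both 3 residual SDs and
  10 lb.  The SD uses the n−1 denominator and is computed from all
  residuals, including the candidate point.  A consequence worth knowing:
  the largest standardized residual among n points is (n−1)/√n, which is
  below 3 for n ≤ 10, so a *single* spike can only be flagged in records
  of 11+ entry days (and a 3-entry record interpolates exactly and can
  never flag).  Deletion (leave-one-out) residuals would behave
  differently; they are deliberately not used.
* **F2 (daily rate)** flags both entries of any consecutive date-sorted
  pair whose change exceeds 2% of the earlier weight per day (strict
  inequality), with the earlier weight as denominator.  Because the day
  gap is unbounded, slow drifts over long gaps are also screened.
* **F3 (pairwise jump)** flags both entries of *every* pair — not only
  consecutive ones — differing by 50 lb or more (inclusive).
* **F4 (record range)** is member-level: max − min ≥ 100 lb (inclusive)
  over the whole record, materialized on the argmin/argmax entries so the
  review workflow has concrete entries to adjudicate.  Max − min is used
  rather than last − first, which would miss interior spikes.

F1-F3 require ≥ 3 entry days; F4 requires ≥ 2.  All thresholds live in
`QCThresholds` as configuration, not constants.

Flags go to two independent reviewers.  `resolve_reviews` computes raw
agreement and Cohen's kappa, κ = (p_o − p_e)/(1 − p_e) with p_e from the
reviewers' marginal verdict frequencies, requires a consensus verdict for
every disagreement, and confirms as erroneous the concordant-erroneous
plus consensus-erroneous entries.  Only confirmed entries are removed;
the tool never auto-adjudicates.  In fully simulated runs the reviewers
are emulated: each labels a flagged entry according to ground truth with
an independent 2.5% flip probability, and consensus resolves to truth.
At a ~24% erroneous base rate this reproduces agreement ≈ 0.95 and
κ ≈ 0.9; when the flag set is dominated by valid-but-extreme
trajectories (see *Known behaviours* below) the same flip rate yields a
much lower κ, because κ is base-rate sensitive.

## Cohort and outcomes

Members need ≥ 2 distinct weigh-in days after cleaning.  The temporality
rule keeps members whose last log-in is on or before their last weigh-in;
since every site activity generates a log-in, this guarantees all feature
use happened between the first and last weight entries, so engagement
precedes the measured outcome.  A `FlowLedger` enforces conservation
(entering = retained + excluded) at every stage.

The baseline weight is the *first cleaned weight entry*, not the roster
registration weight (which serves only baseline exclusions); weight change
is defined from entries, so the first entry is the natural origin.
Outcomes per member: net change (kg) = (last − first entry in lb) ×
0.45359237; weight-entry span = days between first and last entry; change
per 30 days = net ÷ (span/30).  BMI uses the imperial formula
703 · lb / in².  Span strata for the descriptive table use
inclusive upper bounds (≤30, 31-60, 61-90, 91-183, 184-365, 366-548,
549-829 days, plus an open-ended catch-all).

## Engagement coding

Binary flags are ever/never per feature (log-in days, weigh-in days, and
activity points are excluded from the binary analysis: cohort members all
have ≥ 2 log-ins and weigh-ins, and nearly everyone earns points).
Categorical coding divides counts by span/30, sharing the outcome's
exposure denominator: log-in, weigh-in, food, exercise and forum
variables split at 4 events/30 d (≈ weekly), exercise minutes at
120 min/30 d, points at 20/30 d.  The "0" level requires an exactly zero
count; "≥" thresholds are inclusive; log-in and weigh-in variables have
no zero level (impossible in the cohort).  The friend count is
categorized raw (0 / 1 / ≥2), not per-30-days — a friendship is a state,
not a recurring event.

## Regression

All models are OLS with classical standard errors and t-based 95% CIs.
The confounder screen fits each candidate (baseline BMI, age, sex,
registration source, region, span) alone against net change and retains
those with overall p < .05 (categoricals judged by the model F-test).
Univariable engagement models adjust for the screened confounders; binary
predictors use the net-change (kg) outcome, categorical predictors the
per-30-day outcome, and coefficients are contrasts against the least-use
reference level.  Backward stepwise selection starts from baseline BMI
plus all categorical usage variables (per-30-day outcome), repeatedly
removes the variable with the largest joint (block F) p ≥ .20 — ties
broken by removing the later-declared variable, for determinism — and
refits until all survivors sit below the threshold.  BMI is removable
like any other term.  Empty category levels are dropped and reported as
not estimable; a rank-deficient full model raises an error naming the
terms rather than silently pivoting.

A null covariate's p-value is ~Uniform(0,1), so backward elimination at
p ≥ .20 leaves a pure-noise variable in the final model about 20% of the
time.  That is a property of the selection rule, not a defect of the
implementation, and the selection trace makes such survivors auditable.

## Synthetic-data generator

The generator emulates the structure of a free online weight-loss
program's event logs.  Roster: ~90.7% female; age from a truncated normal
33.6 (SD 11, bounds 18-100); BMI truncated normal 31.6 (SD 7.7); heights
sex-specific within 49-78 in; baseline weight derived from BMI and
height; registration uniform over a 90-day window with follow-up to day
830.  Dates are integer day offsets; ISO-8601 only at I/O.

Members belong to a small "frequent-weigher" stratum or a casual
majority.  Attrition is a per-log-in geometric stopping process; log-in
gaps are shifted-geometric; each log-in after the first (which always
records the baseline weight) weighs in with a class-specific propensity,
and extra browse-only visits can fall between log-ins.  This yields the
characteristic funnel: most members record one or two weigh-ins, usage
totals are right-skewed with point masses at zero for social features,
and log-in days always dominate weigh-in days.

Weight trajectories combine (i) a per-member drift (kg/30 d) equal to an
intercept (−0.15) plus `true_beta_weigh_freq` (−5.09) if the member's
*realized* weigh-in rate is ≥ 4/30 d, plus N(0, `drift_sd`) heterogeneity,
with the drift flattening after a 180-day plateau (the familiar
six-month plateau of active weight loss); (ii) a Brownian wander sampled
at weigh-in days, whose variance grows linearly in time — chosen over a
deterministic piecewise line with i.i.d. noise because the spread of
total weight change in such cohorts grows roughly with the square root
of the span; (iii) one-time net shifts after the baseline entry of
`beta_bmi` (−0.28 kg per BMI unit) and `beta_forum` (−1.55 kg for any
forum post), applied as centered contrasts so they shift group
differences, not the population mean trajectory; and (iv) i.i.d. 1-lb
measurement noise per entry.  Trajectories respect a 25-kg physiological
floor.  All randomness flows from one master seed through fixed
substreams, and identical configurations reproduce byte-identical CSVs.

Injected data-entry errors corrupt exactly `round(error_rate · n)`
entries (default 0.2%) by omitting a digit (185 → 18), inserting a digit,
transposing the two leading digits (185 → 815), or jumping by ±50-100% of
the current weight.  A corruption must change the value and keep it
positive; an operation that cannot (transposing equal digits, say) is
resampled.  Every corruption is recorded in a ground-truth table.

### The two study conditions

* **Funnel condition** (`SimConfig()` defaults, n = 26,582): emulates the
  full member funnel with rapid attrition and the error-injection chain;
  used to measure filter sensitivity, removal fractions, review
  statistics, and flow accounting.
* **Cohort-scale recovery condition** (`SimConfig.cohort_scale()`,
  n = 1258): every member has ≥ 4 weigh-in days (weighing at every
  log-in), so all funnel stages pass everyone and the analyzed cohort
  size is exactly n.  The casual stratum's minimum log-in gap of 12 days
  makes a ≥ 4/30 d realized weigh rate arithmetically impossible for
  casual members (30/12 · K/(K−1) < 4 for K ≥ 3), so the weigh-frequency
  contrast is carried by the engaged stratum (~19%, matching the share of
  weekly weighers in such cohorts).  The two strata have comparable span
  distributions, the drift plateau is disabled so the per-30-day truths
  are exact at any span, and the noise mix (rate SD 2.5 kg/30 d, wander
  1 kg/√30 d) keeps the per-30-day regression error dominated by its
  homoskedastic between-member component — the regime in which classical
  OLS intervals are calibrated, making CI-coverage tests a check of the
  estimation chain rather than of a robust-variance choice the model does
  not make.  Error injection is off here: recovery isolates estimation
  from cleaning.

### What the generator does not emulate

Real self-reported weights show digit preference (round-number heaping),
seasonal patterns, autocorrelated measurement conditions (clothing, time
of day), informative missingness (skipping weigh-ins after gains), and
usage variables that causally feed back on behaviour.  Passing tests on
synthetic data therefore demonstrates that the pipeline's arithmetic,
rules, and estimators are correct under the stated generative model —
not that the substantive conclusions would replicate on any particular
real cohort.

## Numerical choices and degenerate inputs

Quadratic fits center the day axis before solving (conditioning only;
flags are shift-invariant).  Filter boundary conventions: F2 is strict
(> 2%/day), F3 and F4 inclusive (≥).  Kappa returns 1 when both
reviewers are constant and identical, and (p_o − p_e)/(1 − p_e)
otherwise.  Rate categories place exact-zero counts in "0" and inclusive
thresholds at the "≥" level.  Span bins are inclusive of printed upper
bounds.  Empty rosters, negative counts, spans below one day, orphan
entries, members with entries but no log-ins, and confirmed-error ids
absent from the input all raise typed exceptions rather than propagating
NaNs.

## Known behaviours and limitations

* Under the funnel condition, F3/F4 flag thousands of entries belonging
  to members whose *genuine* trajectories span ≥ 50 lb; precision of the
  filter union is accordingly low (~1%) and the simulated-review κ is
  much lower than in balanced review sets.  This is the filter doing its
  designed job — deferring large changes to human review — on data whose
  true changes are large.
* Filter sensitivity is reported both overall and among *eligible*
  entries (members with ≥ 2 weigh-in days).  Corruptions landing on
  single-entry members are structurally undetectable by trajectory
  filters, and such members never reach any analysis.
* Problem sizes in the test suite and acceptance script — 26,582 members
  for the funnel run, 20 replicates of n = 1258 for recovery, 10
  replicates for the reported coefficient averages — were chosen to make
  the Monte-Carlo noise small relative to the tolerances being checked.
* The stepwise model's BMI coefficient is on the per-30-day scale and is
  not comparable to the net-change BMI coefficient from the confounder
  screen; only the latter estimates the −0.28 kg/unit generating truth.
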