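# Methods

`smncard` quantifies the excess occurrence of severe cardiac disease
after a second malignant neoplasm (SMN) among 5-year childhood cancer
survivors, under the competing risk of death.  It asks two distinct
questions and answers each with the appropriate estimand:

1. **Does an SMN raise the instantaneous risk of cardiac disease?**
   Cause-specific hazard regression with the SMN as a time-dependent
   exposure (answer: a cause-specific hazard ratio, csHR).
2. **Does an SMN raise the probability of experiencing cardiac
   disease?**  An additive model for the cumulative incidence function
   (CIF), fitted per landmark time on jackknife pseudo-values (answer:
   a difference in cumulative incidence, in percentage points).

The two scales can disagree: an SMN can double the cardiac hazard while
barely moving the cardiac CIF if it also raises mortality, because
deaths remove survivors from cardiac risk.  This is why both analyses
are run, and why death is a competing event rather than censoring.

## Data model

One row per survivor.  Time is measured in years since childhood cancer
diagnosis throughout; attained age is always derived as
`age_at_diagnosis + elapsed time` and never stored.  Cohort entry is at
5 years post-diagnosis (the definition of a 5-year survivor); subjects
whose first event — cardiac disease, death, or loss to follow-up —
occurs before 5 years (or a terminating event at exactly 5 years) are
excluded, and the count is reported.  The outcome is `(T, e)` with `e`
in {cardiac, death_other, censored}; the SMN is an intermediate,
non-terminating state with `5 <= smn_time <= T`.  A tie
`smn_time == T` is resolved as "SMN first" (the subject is exposed at
the event), so ties are deterministic.

Dose categories follow the cohort-description cut-points: anthracycline
0 / (0,100] / (100,250] / >250 mg/m2; mean heart dose 0 / (0,5] /
(5,15] / (15,35] / >35 Gy; mean brain dose 0 / (0,20] / (20,30] /
(30,50] / >50 Gy.  Positive intervals are closed on the right (a
printed "100-250" band contains 250); zero dose is its own category.
Age at diagnosis is banded <5 / [5,10) / [10,15) / >=15 years.
Percentages are rounded half-away-from-zero to one decimal.  Median
follow-up is the median of `T` over all subjects (events and censored
alike); the convention is documented because it is ambiguous in
published descriptions.

## Nonparametric estimation

Overall survival is the product-limit estimator over all-cause events;
the CIF of cause k is the Aalen-Johansen estimator
`F_k(t) = sum_{t_j <= t} S(t_j-) d_kj / n_j`.  Tie conventions are the
standard counting-process ones: events precede censorings at equal
times, and different causes tied at one time share the risk set and the
same left-limit survival.  These make the conservation identity
`S(t) + sum_k F_k(t) = 1` hold exactly, which the tests assert to
1e-10.  Left truncation (delayed entry) is supported through
entry-time-aware risk sets and is what makes attained-age analyses
well-defined.

The pointwise CIF variance is the delta-method (Aalen-type) estimator

    Var F1(t) = sum_j (F1(t)-F1(t_j))^2 d_j / (n_j (n_j - d_j))
              + sum_j S(t_{j-1})^2 (n_j - d_1j) d_1j / n_j^3
              - 2 sum_j (F1(t)-F1(t_j)) S(t_{j-1}) d_1j / n_j^2 ,

which reduces to the binomial variance without censoring; the tests
verify its confidence-interval half-width against a leave-one-out
jackknife within 15% at n = 200.  Intervals are symmetric normal,
truncated to [0, 1].

## Pseudo-observations

For subject i and grid time t,
`PV_i(t) = n F(t) - (n-1) F^(-i)(t)` with `F` the Aalen-Johansen CIF.
Subjects sharing an identical `(time, cause)` pair have identical
leave-one-out estimates, so the computation collapses to one
re-estimation per distinct pair — an exact grouping, verified against a
per-subject brute-force jackknife to 1e-10 with censoring, competing
events and ties.  Without censoring the pseudo-values reduce exactly to
event indicators.  With heavy censoring they legitimately leave [0, 1]
and are never clipped.  A diagnostic warning is emitted when fewer than
a configurable minimum (default 5) events of the cause precede the
first or follow the last grid time, since the grid should sit inside
the event support.  Pseudo-values for landmark datasets are computed on
the residual time scale (time since the landmark), equivalent to the
original scale restricted to t > s up to relabelling.

## Landmarking

A landmark dataset at time s keeps subjects event-free and under
observation at s, freezes `X_SMN(s) = 1(smn_time <= s)` (closed at s:
an SMN diagnosed at the landmark is known at the landmark) and measures
residual time from s.  On the attained-age scale a subject qualifies
only if their entry age (`age_at_diagnosis + 5`) is at or below s —
landmark conditioning is ill-defined for subjects not yet under
observation; this inclusion rule is a package decision where published
practice is silent.  Exposure can alternatively be coded by SMN type
(no SMN / breast, women / sarcoma-bone-soft-tissue / other or unknown).
Each landmark is fitted separately; no super-model smoothing across
landmarks is attempted.

## Additive CIF regression

Per landmark, the model is `F_s(t) + X_SMN(s) b_SMN + X b` on the grid
of post-landmark times (default 2, 4, ..., 20 years): one free
intercept per grid time (the baseline CIF) and time-constant additive
covariate effects on the probability scale.  With identity link and an
independence working correlation, the generalized-estimating-equation
fit on the stacked subject-by-grid pseudo-values is exactly ordinary
least squares on the stacked data; this equivalence is what the
implementation uses.  The variance is the subject-clustered sandwich
with the standard finite-sample scaling `(N-1)/(N-p) * G/(G-1)`; it is
verified against an independent dense-matrix cluster-covariance oracle.
Effects are reported as percentage points (100x the probability-scale
coefficient).  The reported `excess events` translation is
`n_exposed * b_SMN` (and `n_exposed * CIF_exposed` for the expected
count), rounded to one decimal.

Covariate sets: `univariable` (exposure only), `binary_adjusted`
(+ sex, age-at-diagnosis categories, diagnosis era before/after 1980,
radiotherapy yes/no, chemotherapy yes/no), and `dose_adjusted` (+ sex,
age categories, era, alkylating agent, platinum agent, neck
radiotherapy, and categorical anthracycline and heart/brain dose).
Doses enter as the Table-style categories with the zero-dose category
as reference — a deliberately conservative functional form.

## Cause-specific hazards

Survivors contribute counting-process episodes on (start, stop] with
delayed entry at 5 years, split exactly at the SMN time; the competing
event censors the cause-specific episode.  The partial likelihood with
delayed-entry risk sets is maximised by Newton-Raphson with
step-halving; ties use the Efron correction by default (Breslow
available; the two agree exactly without ties, and episode splitting at
any non-event time leaves the likelihood invariant to 1e-10 — both
tested).  The variance is the model-based inverse information, matching
how plain proportional-hazards confidence intervals are reported.
Covariates are centred before fitting (the partial likelihood is
invariant; conditioning improves), and convergence is declared at score
sup-norm < 1e-8 with a step-size fallback for when the score reaches
the floating-point floor of the risk-set sums.  A coefficient diverging
past |b| > 10 is flagged as a possible monotone likelihood
(separation) rather than reported silently; design columns without
variation are dropped and reported as inestimable (e.g. a breast-SMN
term in a cohort with no breast SMNs).

## The synthetic cohort generator

Because the motivating cohort is not public, every stage is exercised
on a parametric Markov (clock-forward) illness-death model with
competing risks: healthy -> SMN (intermediate) and healthy/SMN ->
cardiac disease or death, with piecewise-constant baseline hazards on
time since diagnosis and proportional covariate effects, so the
time-dependent Cox stage is correctly specified by construction.  After
an SMN the cardiac and death hazards are multiplied by
`theta_cd_after_smn` and `theta_death_after_smn` — the ground-truth
csHRs.  Sampling inverts the piecewise cumulative hazard; the uniform
draws form a fixed-shape matrix (one column per transition), so
scenarios sharing a seed and cohort size are coupled by common random
numbers, which sharpens scenario comparisons.

Exact model-implied quantities are available by piecewise
matrix-exponential propagation of the state-occupation vector:
marginal CIFs, SMN prevalence, and landmark-conditional CIF contrasts
(profiles weighted by their probability of occupying the conditioning
state at s).  These serve as calibration targets and as the ground
truth for recovery tests — the additive stage is evaluated against the
model's own (mildly time-varying) CIF contrast, whose equal-weight grid
average is what the constant-coefficient model estimates.

**Default calibration.**  The default parameter set was calibrated with
the exact integrator (bisection on one rate at a time, iterated to
joint convergence) so that, marginally over covariates, the cardiac CIF
is 0.039 at 30 years and 0.084 at 50 years since diagnosis, death
reaches about 0.13/0.30 at 30/50 years, and about 10% of survivors have
experienced an SMN by 30 years.  The resulting baseline rates are
SMN 3.597e-3 /yr; cardiac 9.22e-4 /yr before 30 years and 1.661e-3
after; death 5.212e-3 and 9.763e-3.  Ground-truth multipliers are
theta_cd = 2.0 and theta_death = 3.0 (an SMN raises mortality more than
cardiac risk).  Covariate effects are plausible magnitudes for the
known risk factors (heart dose >5 Gy: log-HR 1.10 on cardiac;
anthracycline >100 and >250 mg/m2: 0.40 and 0.55 cumulative; smaller
effects on death and SMN).  Covariates are sampled independently with
marginal frequencies matching the published cohort description — the
joint distribution is not modelled, a documented simplification.
Censoring combines a fixed end of follow-up in 2016 (diagnosis year
uniform on 1945-2000) with exponential loss to follow-up at 0.008/yr,
tuned so the median follow-up is about 30 years; the IQR is somewhat
wider than in the real cohort because accrual is uniform.

**What passing tests do and do not show.**  The generator reproduces
marginal covariate frequencies, headline incidences and the multistate
structure; it does not reproduce covariate dependence, non-proportional
treatment effects, era effects on hazards, or informative censoring.
Recovery tests therefore demonstrate the estimators' correctness under
a correctly specified (hazard scale) or mildly misspecified (additive
scale) data-generating process, not robustness to real-data violations.

**Recovery-test conditions.**  Monte-Carlo recovery uses a scenario
with the same structure but denser events (cardiac 5e-3 /yr, death
8e-3 /yr, SMN 1.8e-2 /yr, 40-year horizon), so that a desk-scale
n = 2,000 cohort yields enough post-landmark cardiac events per
exposure group for the asymptotic variance to be meaningful; with the
sparse default rates the exposed-group event counts at n = 2,000 are in
the single digits and Wald intervals on pseudo-value fits are known to
undercover.  Coverage of the cluster sandwich remains slightly below
nominal (≈0.92 observed at n = 2,000), consistent with the known
finite-sample behaviour of unadjusted sandwich estimators.  Problem
sizes used by the test-suite recovery checks: 200 replicates of
n = 2,000 (additive coverage and null type-I error), 50 replicates of
n = 2,000 plus one n = 5,000 run (csHR), and one n = 50,000 cohort
(calibration); the acceptance script uses n = 50,000 for calibration
and four replicates of n = 10,000 for the regression stages.

## Known limitations

- No Fine-Gray subdistribution model: effects on the CIF are estimated
  additively via pseudo-values, effects on rates via cause-specific
  hazards, and the two are interpreted jointly.
- No smoothing of effects across landmarks, no multiple-testing
  adjustment, no time-varying coefficients or frailties.
- Pseudo-value inference assumes censoring independent of covariates;
  the sandwich is mildly anti-conservative in small samples.
- The simulator's independent-covariate and uniform-accrual
  simplifications mean descriptive joint distributions (e.g. treatment
  combinations by era) should not be read as realistic.
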