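# smncard

Childhood cancer survivors carry two of the most serious late effects of
their treatment: second malignant neoplasms (SMNs) and severe cardiac
disease.  `smncard` quantifies how much *extra* cardiac disease follows
an SMN, treating death from other causes as a competing event and the
SMN itself as a time-dependent exposure rather than an endpoint.  It is
aimed at biostatisticians and epidemiologists working with long-term
survivorship cohorts (one row per survivor: treatment exposures,
optional SMN time/type, and a right-censored time-to-first-event
outcome with cause labels).

Two complementary estimands are implemented:

- **Cause-specific hazard ratio (csHR).**  A proportional cause-specific
  hazards model on counting-process episodes `(start, stop]` with
  delayed entry at 5 years post-diagnosis and the SMN indicator
  `X_SMN(t) = 1(SMN before t)` switching within subject — the effect of
  an SMN on the *instantaneous* risk of cardiac disease.
- **Additive excess cumulative incidence.**  At each landmark time `s`
  (survivors event-free at `s`, exposure frozen at `s`), the model

      P(T <= t, e = cardiac | T > s, X) = F_s(t) + X_SMN(s) b_SMN + X b

  is fitted on Aalen-Johansen jackknife pseudo-values at a grid of
  post-landmark times, by identity-link estimating equations
  (equivalently, stacked least squares) with a subject-clustered
  sandwich variance.  `b_SMN` is the extra probability of cardiac
  disease attributable to an SMN, in percentage points — directly
  interpretable and convertible to excess event counts.

The hazard and probability scales can genuinely disagree (an SMN that
doubles the cardiac hazard may add little cumulative incidence if it
raises mortality even more), which is why both are provided.

Because real survivorship cohorts of this kind are not public, the
package ships a calibrated multistate illness-death simulator with
known ground truth (cause-specific hazard multipliers after an SMN,
exact model-implied cumulative incidence via matrix-exponential
integration), so every stage is testable end-to-end.

## Worked example

```python
import numpy as np, warnings
from smncard import (default_fccss_like_params, simulate_cohort,
                     apply_five_year_exclusion, stacked_incidence,
                     build_landmark, pseudo_values, fit_additive,
                     excess_events, episodes_from_cohort, fit_cox)

cohort = simulate_cohort(default_fccss_like_params())   # 7,670 survivors
cohort, _ = apply_five_year_exclusion(cohort)

stk = stacked_incidence(cohort)
print(stk.at_years.round(4))
#       cause  time    cif     se     lo     hi
#     cardiac  30.0 0.0366 0.0024 0.0320 0.0413
#     cardiac  50.0 0.0870 0.0045 0.0782 0.0958
# death_other  30.0 0.1295 0.0043 0.1212 0.1379
# death_other  50.0 0.2957 0.0074 0.2811 0.3103

ds = build_landmark(cohort, s=25.0)                     # 4,674 at risk, 412 exposed
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    pv = pseudo_values(ds, "cardiac", np.arange(2.0, 21.0, 2.0))
fit = fit_additive(ds, pv, "dose_adjusted")
print(fit.summary_frame().head(1).round(3))
#  term  estimate_pct  se_pct  ci_lo_pct  ci_hi_pct      p
#   smn         0.710   0.810     -0.879      2.298  0.381
print(excess_events(ds.n_exposed, fit.coef[0]).excess)  # 2.9

cox = fit_cox(episodes_from_cohort(cohort, "cardiac"), "dose_adjusted")
print(cox.summary_frame().query("term == 'smn'").round(3))
#  term   coef     se     hr  hr_lo  hr_hi    p
#   smn  0.624  0.136  1.867  1.431  2.435  0.0
```

Reading the output: in this simulated cohort (ground-truth csHR 2.0 for
cardiac disease and 3.0 for death after an SMN), the cumulative
incidence of cardiac disease is 3.7% at 30 years and 8.7% at 50 years;
among survivors event-free 25 years after diagnosis, an SMN adds an
estimated 0.7 percentage points of cardiac incidence (about 3 excess
events among the 412 exposed, not significant at this size), while the
adjusted cause-specific hazard ratio is 1.87 (95% CI 1.43-2.43) —
the hazard effect is recovered, and the small additive effect reflects
the strong competing mortality after an SMN.

A full analysis bundle (descriptives, stacked incidence, landmark
additive suite on both time scales, Cox suite, tidy CSVs, JSON summary,
run log) comes from the CLI:

```sh
smncard demo --out results_demo --n 7670 --seed 20230701
smncard run --config my_config.yaml        # on your own cohort CSV
```

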