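"""Cause-specific hazards with a time-dependent exposure."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from smncard.coxph import (episodes_from_cohort, fit_cox, null_loglik,
                           run_csh_suite)
from smncard.simulate import default_fccss_like_params, simulate_cohort
from smncard.cohort import apply_five_year_exclusion

from conftest import make_cohort


def analytic_four_subject():
    eps = pd.DataFrame({
        "subject_id": list("abcd"),
        "start": [0.0, 0.0, 0.0, 0.0],
        "stop": [2.0, 1.0, 3.0, 3.0],
        "event": [1, 1, 0, 0],
    })
    X = pd.DataFrame({"x": [1.0, 0.0, 1.0, 0.0]})
    return eps, X


def test_analytic_four_subject_estimate():
    eps, X = analytic_four_subject()
    fit = fit_cox(eps, design=X)
    assert fit.coef[0] == pytest.approx(-0.5 * np.log(2), abs=1e-6)
    assert fit.hazard_ratio[0] == pytest.approx(2 ** -0.5, abs=1e-6)


def test_breslow_equals_efron_without_ties():
    eps, X = analytic_four_subject()
    a = fit_cox(eps, design=X, ties="efron")
    b = fit_cox(eps, design=X, ties="breslow")
    assert a.coef[0] == pytest.approx(b.coef[0], abs=1e-10)
    assert a.loglik == pytest.approx(b.loglik, abs=1e-10)


def test_split_invariance_of_partial_likelihood():
    eps, X = analytic_four_subject()
    fit = fit_cox(eps, design=X)
    # split subject c's episode [0, 3] at the non-event time 1.7
    eps2 = pd.DataFrame({
        "subject_id": list("ab") + ["c", "c", "d"],
        "start": [0.0, 0.0, 0.0, 1.7, 0.0],
        "stop": [2.0, 1.0, 1.7, 3.0, 3.0],
        "event": [1, 1, 0, 0, 0],
    })
    X2 = pd.DataFrame({"x": [1.0, 0.0, 1.0, 1.0, 0.0]})
    fit2 = fit_cox(eps2, design=X2)
    assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-10)
    assert fit2.coef[0] == pytest.approx(fit.coef[0], abs=1e-10)


def test_null_partial_likelihood_hand_value():
    eps, _ = analytic_four_subject()
    # no ties: l(0) = -log 4 - log 3
    assert null_loglik(eps) == pytest.approx(-np.log(4) - np.log(3), abs=1e-12)


def test_episode_construction_and_person_time():
    cohort = make_cohort([30.0, 30.0, 25.0], ["cardiac", "death_other", "cardiac"],
                         smn_times=[18.0, None, 25.0])
    eps = episodes_from_cohort(cohort, "cardiac")
    s0 = eps[eps["subject_id"] == "s0"].sort_values("start")
    assert list(s0["start"]) == [5.0, 18.0]
    assert list(s0["stop"]) == [18.0, 30.0]
    assert list(s0["event"]) == [0, 1]
    assert list(s0["exposure"]) == [0, 1]
    # competing event censors the cause-specific episode
    s1 = eps[eps["subject_id"] == "s1"]
    assert list(s1["event"]) == [0] and list(s1["exposure"]) == [0]
    # SMN exactly at T: single fully exposed episode
    s2 = eps[eps["subject_id"] == "s2"]
    assert len(s2) == 1 and s2["exposure"].iloc[0] == 1 and s2["event"].iloc[0] == 1
    exposed_pt = (eps.loc[eps["exposure"] == 1, "stop"]
                  - eps.loc[eps["exposure"] == 1, "start"]).sum()
    assert exposed_pt == pytest.approx((30 - 18) + (25 - 5))


def test_time_fixed_equivalence_with_lifelines():
    # no SMN in the cohort: the episode fit must equal a standard
    # right-censored, delayed-entry Cox fit on the unsplit data
    cohort = simulate_cohort(default_fccss_like_params(n_subjects=1500, seed=41))
    df = cohort.df.copy()
    df["smn_time"] = np.nan
    df["smn_type"] = "none"
    from smncard.cohort import Cohort
    cohort = Cohort.from_frame(df)
    cohort, _ = apply_five_year_exclusion(cohort)
    eps = episodes_from_cohort(cohort, "cardiac")
    from smncard._designs import build_design
    Z = build_design(eps, "binary_adjusted").drop(columns=["smn"])
    fit = fit_cox(eps, design=Z)

    ll_df = pd.concat([
        eps[["start", "stop", "event"]].reset_index(drop=True),
        Z.reset_index(drop=True)], axis=1)
    cph = CoxPHFitter()
    cph.fit(ll_df, duration_col="stop", event_col="event", entry_col="start",
            fit_options={"precision": 1e-9})
    np.testing.assert_allclose(
        fit.coef, cph.params_[fit.terms].values, atol=1e-6)


def test_monotone_likelihood_flagged_not_silent():
    eps = pd.DataFrame({
        "subject_id": list("abcd"),
        "start": [0.0] * 4,
        "stop": [1.0, 2.0, 3.0, 3.0],
        "event": [1, 1, 0, 0],
    })
    X = pd.DataFrame({"x": [1.0, 1.0, 0.0, 0.0]})
    fit = fit_cox(eps, design=X)
    assert not fit.converged
    assert any("monotone" in w for w in fit.warnings)


def test_inestimable_level_flagged():
    cohort = make_cohort([30.0, 28.0, 26.0, 24.0],
                         ["cardiac", "censored", "cardiac", "censored"],
                         smn_times=[15.0, 14.0, None, None])
    eps = episodes_from_cohort(cohort, "cardiac", exposure_mode="by_type")
    fit = fit_cox(eps, covset="univariable", exposure_mode="by_type")
    assert "smn_breast_female" in fit.inestimable
    assert "smn_other_unknown" in fit.terms
    summ = fit.summary_frame()
    assert summ.loc[summ["term"] == "smn_breast_female", "coef"].isna().all()


def test_validation_errors():
    eps, X = analytic_four_subject()
    bad = eps.copy()
    bad.loc[0, "stop"] = 0.0
    with pytest.raises(ValueError, match="start < stop"):
        fit_cox(bad, design=X)
    none = eps.copy()
    none["event"] = 0
    with pytest.raises(ValueError, match="no events"):
        fit_cox(none, design=X)


def test_suite_composition_and_error_isolation():
    cohort = simulate_cohort(default_fccss_like_params(n_subjects=1200, seed=42))
    cohort, _ = apply_five_year_exclusion(cohort)
    res = run_csh_suite(cohort, covsets=("univariable",),
                        causes=("cardiac", "death_other"))
    direct = fit_cox(episodes_from_cohort(cohort, "cardiac"), "univariable")
    row = res[(res["cause"] == "cardiac") & (res["term"] == "smn")].iloc[0]
    assert row["hr"] == pytest.approx(direct.hazard_ratio[
        direct.terms.index("smn")], abs=1e-10)
    assert (res["cause"] == "death_other").any()
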