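"""Additive cumulative-incidence regression on pseudo-values."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import warnings

from smncard.additive import (RankDeficientError, excess_events, fit_additive,
                              run_landmark_suite)
from smncard.incidence import aalen_johansen_arrays
from smncard.landmark import build_landmark
from smncard.pseudo import pseudo_values
from smncard.simulate import default_fccss_like_params, simulate_cohort

from conftest import make_cohort, random_survival_data


def landmark_with_pv(cohort, s, grid, cause="cardiac", exposure_mode="binary"):
    ds = build_landmark(cohort, s, exposure_mode=exposure_mode)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pv = pseudo_values(ds, cause, np.asarray(grid, float))
    return ds, pv


def test_intercept_only_recovers_empirical_cif(rng):
    # uncensored: stacked least squares on indicator pseudo-values gives
    # the empirical CIF at each grid time exactly
    times = rng.exponential(8, size=40) + 6.0
    causes = np.where(rng.uniform(size=40) < 0.4, "death_other", "cardiac")
    cohort = make_cohort(times, causes)
    grid = [2.0, 5.0, 9.0]
    ds, pv = landmark_with_pv(cohort, 6.0, grid)
    # no exposed subjects -> exposure column dropped via rank error; use a
    # design of intercepts only by fitting on an all-zero exposure with
    # one exposed subject removed: instead check against AJ on residual data
    est = aalen_johansen_arrays(ds.df["time"].values, ds.df["cause"].values)
    fit = fit_additive_no_exposure(ds, pv)
    for k, t in enumerate(grid):
        assert fit[k] == pytest.approx(est.cif_at(t, "cardiac"), abs=1e-10)


def fit_additive_no_exposure(ds, pv):
    # intercept-only stacked least squares (baseline CIF per grid time)
    n, m = pv.values.shape
    y = pv.values.reshape(-1)
    X = np.tile(np.eye(m), (n, 1))
    return np.linalg.lstsq(X, y, rcond=None)[0]


def test_two_group_single_time_worked_example():
    # group0 events {1,5}, group1 events {1,2} on the residual scale,
    # all cardiac, grid t=3
    cohort = make_cohort([7.0, 11.0, 7.0, 8.0], ["cardiac"] * 4,
                         smn_times=[None, None, 5.5, 5.5])
    ds, pv = landmark_with_pv(cohort, 6.0, [3.0])
    fit = fit_additive(ds, pv, "univariable")
    assert fit.baseline[0] == pytest.approx(0.5, abs=1e-10)
    assert fit.coef[fit.terms.index("smn")] == pytest.approx(0.5, abs=1e-10)


def test_single_grid_time_equals_group_mean_difference(rng):
    n = 60
    times = rng.exponential(12, size=n) + 5.5
    causes = np.where(rng.uniform(size=n) < 0.5, "cardiac", "censored")
    smn = [6.0 if (u < 0.4 and t > 6.0) else None
           for u, t in zip(rng.uniform(size=n), times)]
    cohort = make_cohort(times, causes, smn_times=smn)
    ds, pv = landmark_with_pv(cohort, 7.0, [6.0])
    fit = fit_additive(ds, pv, "univariable")
    g = ds.df["exposure"].values
    direct = pv.values[g == 1, 0].mean() - pv.values[g == 0, 0].mean()
    assert fit.coef[fit.terms.index("smn")] == pytest.approx(direct, abs=1e-10)


def test_sandwich_matches_statsmodels_cluster_oracle():
    cohort = simulate_cohort(default_fccss_like_params(n_subjects=600, seed=31))
    ds, pv = landmark_with_pv(cohort, 15.0, [2.0, 4.0, 6.0])
    fit = fit_additive(ds, pv, "binary_adjusted")
    n, m = pv.values.shape
    from smncard._designs import build_design
    Z = build_design(ds.df, "binary_adjusted", "binary").values
    X = np.hstack([np.tile(np.eye(m), (n, 1)), np.repeat(Z, m, axis=0)])
    res = sm.OLS(pv.values.reshape(-1), X).fit(
        cov_type="cluster", cov_kwds={"groups": np.repeat(np.arange(n), m),
                                      "df_correction": False})
    np.testing.assert_allclose(fit.coef, res.params[m:], atol=1e-8)
    np.testing.assert_allclose(fit.robust_se, res.bse[m:], atol=1e-8)


def test_estimates_invariant_to_subject_order():
    cohort = simulate_cohort(default_fccss_like_params(n_subjects=500, seed=32))
    perm = cohort.df.sample(frac=1.0, random_state=7).reset_index(drop=True)
    from smncard.cohort import Cohort
    shuffled = Cohort.from_frame(perm)
    a = landmark_with_pv(cohort, 15.0, [2.0, 5.0])
    b = landmark_with_pv(shuffled, 15.0, [2.0, 5.0])
    fa = fit_additive(*a, "univariable")
    fb = fit_additive(*b, "univariable")
    assert fa.coef[fa.terms.index("smn")] == pytest.approx(
        fb.coef[fb.terms.index("smn")], abs=1e-10)


def test_rank_deficiency_names_column():
    cohort = make_cohort([10.0, 12.0, 14.0, 16.0], ["cardiac"] * 4,
                         smn_times=[6.0, 6.0, 6.0, 6.0])  # everyone exposed
    ds, pv = landmark_with_pv(cohort, 7.0, [5.0])
    with pytest.raises(RankDeficientError, match="smn"):
        fit_additive(ds, pv, "univariable")


def test_mismatched_subjects_rejected():
    cohort = make_cohort([10.0, 12.0, 14.0], ["cardiac"] * 3,
                         smn_times=[6.0, None, None])
    ds, pv = landmark_with_pv(cohort, 7.0, [5.0])
    ds2 = build_landmark(cohort, 8.0)
    ds2.df = ds2.df.iloc[:2]
    with pytest.raises(ValueError, match="match"):
        fit_additive(ds2, pv, "univariable")


def test_excess_events_worked_examples():
    ex = excess_events(259, 0.038, cif_exposed=0.115)
    assert ex.excess == 9.8
    assert ex.expected == 29.8
    assert excess_events(0, 0.5).excess == 0.0
    with pytest.raises(ValueError):
        excess_events(-1, 0.1)


def test_suite_composition_and_percent_scale():
    cohort = simulate_cohort(default_fccss_like_params(n_subjects=800, seed=33))
    res = run_landmark_suite(cohort, [15.0], covsets=("univariable",),
                             grid=[2.0, 4.0, 6.0])
    ds, pv = landmark_with_pv(cohort, 15.0, [2.0, 4.0, 6.0])
    fit = fit_additive(ds, pv, "univariable")
    i = fit.terms.index("smn")
    row = res[(res["term"] == "smn")].iloc[0]
    assert row["estimate_pct"] == pytest.approx(100 * fit.coef[i], abs=1e-10)
    # empty landmarks are skipped, not fatal
    res2 = run_landmark_suite(cohort, [15.0, 200.0], covsets=("univariable",),
                              grid=[2.0, 4.0])
    assert set(res2["s"]) == {15.0}
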