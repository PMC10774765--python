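"""Multistate simulator: trivial laws, closed forms, neutrality, defaults."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from smncard.cohort import median_followup
from smncard.incidence import aalen_johansen
from smncard.simulate import (CensoringSpec, ConfigurationError,
                              PiecewiseHazard, SimulationParams,
                              conditional_cif, default_fccss_like_params,
                              expected_cif, expected_smn_prevalence,
                              sample_piecewise_exponential, simulate_cohort)


def flat_params(n=100, seed=1, smn=0.0, cd=0.0, dth=0.0, horizon=40.0, **kw):
    return SimulationParams(
        n_subjects=n, seed=seed,
        smn_hazard=PiecewiseHazard.constant(smn),
        cardiac_hazard=PiecewiseHazard.constant(cd),
        death_hazard=PiecewiseHazard.constant(dth),
        censoring=CensoringSpec(admin_horizon=horizon), **kw)


@pytest.mark.parametrize("bad", [
    dict(n_subjects=0),
    dict(theta_cd_after_smn=-1.0),
    dict(covariate_effects={"nope": {"female": 1.0}}),
    dict(smn_type_probs={"female": {"breast_female": 0.5}}),
])
def test_invalid_params_rejected(bad):
    kwargs = dict(n_subjects=10, seed=1,
                  smn_hazard=PiecewiseHazard.constant(0.1),
                  cardiac_hazard=PiecewiseHazard.constant(0.1),
                  death_hazard=PiecewiseHazard.constant(0.1))
    kwargs.update(bad)
    with pytest.raises(ConfigurationError):
        SimulationParams(**kwargs)


def test_piecewise_hazard_validation():
    with pytest.raises(ConfigurationError):
        PiecewiseHazard(rates=(0.1, 0.2))  # breakpoint count mismatch
    with pytest.raises(ConfigurationError):
        PiecewiseHazard(rates=(-0.1,))


def test_piecewise_exponential_inversion_matches_exponential(rng):
    # constant hazard from t0: t - t0 ~ Exp(rate * mult)
    u = rng.uniform(size=20000)
    t = sample_piecewise_exponential(u, 5.0, PiecewiseHazard.constant(0.2), 2.0)
    samples = t - 5.0
    assert abs(samples.mean() - 1 / 0.4) < 3 * samples.std() / np.sqrt(len(samples))
    # piecewise: zero rate early means no events before the breakpoint
    h = PiecewiseHazard(rates=(0.0, 1.0), breakpoints=(10.0,))
    t2 = sample_piecewise_exponential(u, 5.0, h, 1.0)
    assert (t2 >= 10.0).all()


def test_all_hazards_zero_censored_at_horizon():
    cohort = simulate_cohort(flat_params(n=50, horizon=40.0))
    assert (cohort.df["T"] == 45.0).all()
    assert (cohort.df["e"] == "censored").all()


def test_overwhelming_cardiac_hazard():
    cohort = simulate_cohort(flat_params(n=50, cd=10.0))
    assert (cohort.df["e"] == "cardiac").all()
    assert (cohort.df["T"] - 5.0 < 2.0).all()


def test_determinism_given_seed():
    p = default_fccss_like_params(n_subjects=500, seed=99)
    pd.testing.assert_frame_equal(simulate_cohort(p).df, simulate_cohort(p).df)


def test_closed_form_competing_cif():
    # lam1 = lam2 = 0.5, no SMN: CIF_1(t) = 0.5 (1 - exp(-t))
    p = flat_params(n=50000, seed=3, cd=0.5, dth=0.5, horizon=200.0)
    closed = 0.5 * (1 - np.exp(-(np.array([10.0, 30.0]) - 5.0)))
    np.testing.assert_allclose(expected_cif(p, "cardiac", [10.0, 30.0]),
                               closed, atol=1e-10)
    est = aalen_johansen(simulate_cohort(p))
    for t, target in zip([10.0, 30.0], closed):
        mc_se = np.sqrt(target * (1 - target) / p.n_subjects)
        assert abs(est.cif_at(t, "cardiac") - target) < 3 * mc_se


def test_empirical_hazard_matches_configured_rate():
    p = flat_params(n=50000, seed=4, cd=0.02, dth=0.01, horizon=60.0)
    df = simulate_cohort(p).df
    # interval [5, 10): occurrence/exposure estimate of the cardiac rate
    at_risk = df["T"] >= 5.0
    pt = np.clip(df.loc[at_risk, "T"], None, 10.0) - 5.0
    events = ((df["e"] == "cardiac") & (df["T"] < 10.0)).sum()
    rate = events / pt.sum()
    se = np.sqrt(events) / pt.sum()
    assert abs(rate - 0.02) < 3 * se


def test_neutral_smn_marker_leaves_outcome_law_unchanged():
    # theta factors 1: (T, e) distributed as if the SMN transition were off
    base = flat_params(n=30000, seed=5, cd=0.01, dth=0.01, horizon=45.0)
    with_smn = replace(base, smn_hazard=PiecewiseHazard.constant(0.05),
                       theta_cd_after_smn=1.0, theta_death_after_smn=1.0)
    est_on = aalen_johansen(simulate_cohort(with_smn))
    est_off = aalen_johansen(simulate_cohort(base))
    for t in (15.0, 30.0, 45.0):
        for cause in ("cardiac", "death_other"):
            a, b = est_on.cif_at(t, cause), est_off.cif_at(t, cause)
            mc = np.sqrt(2 * max(a, b) * (1 - min(a, b)) / base.n_subjects)
            assert abs(a - b) < 3 * max(mc, 1e-4)


def test_no_cardiac_event_after_horizon():
    p = flat_params(n=5000, seed=6, cd=0.05, dth=0.02, horizon=30.0)
    df = simulate_cohort(p).df
    assert df.loc[df["e"] == "cardiac", "T"].max() <= 35.0
    assert (df["T"] <= 35.0).all()


def test_smn_observations_consistent():
    p = flat_params(n=5000, seed=8, smn=0.05, cd=0.02, dth=0.02, horizon=40.0,
                    theta_cd_after_smn=2.0)
    df = simulate_cohort(p).df
    has = df["smn_time"].notna()
    assert (df.loc[has, "smn_time"] <= df.loc[has, "T"]).all()
    assert (df.loc[has, "smn_time"] >= 5.0).all()
    assert (df.loc[has, "smn_type"] != "none").all()
    assert (df.loc[(df["smn_type"] == "breast_female"), "sex"] == "female").all()
    emp = has.mean()
    model = expected_smn_prevalence(p, 45.0)  # horizon censoring only
    # censoring trims observation, so observed prevalence <= model and close
    assert emp <= model + 0.01


def test_default_params_documented_targets():
    p = default_fccss_like_params()
    assert p.theta_cd_after_smn == 2.0
    assert p.n_subjects == 7670
    np.testing.assert_allclose(expected_cif(p, "cardiac", [30.0, 50.0]),
                               [0.039, 0.084], atol=5e-4)


def test_default_cohort_median_followup_near_target():
    p = default_fccss_like_params(n_subjects=20000, seed=12)
    fu = median_followup(simulate_cohort(p))
    assert abs(fu.median - 30.0) < 1.5


def test_conditional_cif_consistency_with_marginal():
    # with the SMN transition disabled, conditioning on the healthy state
    # at s is plain Markov conditioning
    p = flat_params(n=10, cd=0.02, dth=0.01, horizon=60.0)
    s, dt = 15.0, np.array([5.0, 10.0])
    cond = conditional_cif(p, s, False, dt, "cardiac")
    lam = 0.03
    closed = (0.02 / lam) * (1 - np.exp(-lam * dt))
    np.testing.assert_allclose(cond, closed, atol=1e-9)
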