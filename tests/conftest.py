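"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from smncard.cohort import Cohort, SubjectRecord


def make_cohort(times, causes, smn_times=None, sexes=None, ages=None, **extra):
    """Minimal valid cohort from outcome arrays (toy-data helper)."""
    n = len(times)
    smn_times = smn_times if smn_times is not None else [None] * n
    records = []
    for i in range(n):
        records.append(SubjectRecord(
            subject_id=f"s{i}",
            sex=(sexes[i] if sexes else "female"),
            age_at_diagnosis=(ages[i] if ages else 5.0),
            T=float(times[i]), e=causes[i],
            smn_time=smn_times[i],
            smn_type=("other_unknown" if smn_times[i] is not None else "none"),
            **extra))
    return Cohort.from_records(records)


def random_survival_data(rng, n, discrete=False, p_censor=0.3, p_compete=0.3):
    """Random (time, cause) arrays with censoring, competing events and
    (optionally) heavy ties."""
    if discrete:
        times = rng.integers(1, 8, size=n).astype(float)
    else:
        times = rng.exponential(10.0, size=n) + 0.5
    u = rng.uniform(size=n)
    causes = np.where(u < p_censor, "censored",
                      np.where(u < p_censor + p_compete, "death_other", "cardiac"))
    return times, causes.astype(object)


def brute_aalen_johansen(times, causes, at, cause="cardiac"):
    """Slow reference Aalen-Johansen: explicit loop over distinct event
    times with events-before-censoring tie handling."""
    times = np.asarray(times, float)
    causes = np.asarray(causes, object)
    ev = np.isin(causes, ["cardiac", "death_other"])
    surv = 1.0
    cif = 0.0
    for t in sorted(set(times[ev])):
        if t > at:
            break
        n_risk = int((times >= t).sum())
        d_all = int((ev & (times == t)).sum())
        d_cause = int(((causes == cause) & (times == t)).sum())
        cif += surv * d_cause / n_risk
        surv *= 1.0 - d_all / n_risk
    return cif


def brute_pseudo_values(times, causes, grid, cause="cardiac"):
    """Direct leave-one-out jackknife pseudo-values (per subject)."""
    times = np.asarray(times, float)
    n = len(times)
    out = np.empty((n, len(grid)))
    full = np.array([brute_aalen_johansen(times, causes, t, cause) for t in grid])
    for i in range(n):
        keep = np.ones(n, bool)
        keep[i] = False
        loo = np.array([brute_aalen_johansen(times[keep], np.asarray(causes)[keep],
                                             t, cause) for t in grid])
        out[i] = n * full - (n - 1) * loo
    return out


@pytest.fixture
def four_subject_example():
    """The hand-computed competing-risks example: cardiac at 1 and 3,
    death at 2, censored at 4."""
    return [1.0, 2.0, 3.0, 4.0], ["cardiac", "death_other", "cardiac", "censored"]


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)
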