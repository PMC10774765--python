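"""Kaplan–Meier overall survival and Aalen–Johansen cumulative incidence
under competing risks, with left truncation and pointwise variances.

Tie convention (standard counting-process): at a tied time, events are
processed before censorings, so subjects censored at an event time are
still in the risk set there; events of different causes at the same time
share the risk set and both jumps use the same left-limit survival
S(t-).  These conventions make the conservation identity
S(t) + sum_k CIF_k(t) = 1 exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import CAUSES, Cohort

__all__ = [
    "CIFEstimate",
    "aalen_johansen",
    "aalen_johansen_arrays",
    "cif_confidence_interval",
    "stacked_incidence",
    "StackedIncidence",
]

EVENT_CAUSES = ("cardiac", "death_other")


@dataclass
class CIFEstimate:
    """Joint product-limit estimate: overall survival and per-cause
    cumulative incidence step functions on the distinct event times."""

    times: np.ndarray                 # distinct all-cause event times
    surv: np.ndarray                  # S(t_j), right-continuous
    cif: dict                         # cause -> CIF_k(t_j)
    n_risk: np.ndarray                # n_j at t_j
    n_event: dict                     # cause -> d_kj at t_j
    n_subjects: int
    entry: np.ndarray | None = None   # left-truncation times, if any
    timescale: str = "since_diagnosis"

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (event time, cause)."""
        rows = []
        for cause, vals in self.cif.items():
            se = np.sqrt(self.variance_at(self.times, cause)) if len(self.times) \
                else np.array([])
            for j, t in enumerate(self.times):
                rows.append({"time": t, "cause": cause, "cif": vals[j],
                             "se": se[j], "n_risk": int(self.n_risk[j])})
        return pd.DataFrame(rows)

    def surv_at(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.atleast_1d(t), side="right") - 1
        out = np.where(idx >= 0, self.surv[np.maximum(idx, 0)], 1.0)
        return out if np.ndim(t) else float(out[0])

    def cif_at(self, t, cause: str) -> np.ndarray:
        idx = np.searchsorted(self.times, np.atleast_1d(t), side="right") - 1
        vals = self.cif[cause]
        out = np.where(idx >= 0, vals[np.maximum(idx, 0)], 0.0)
        return out if np.ndim(t) else float(out[0])

    def variance_at(self, t, cause: str) -> np.ndarray:
        """Pointwise delta-method (Aalen-type) variance of the CIF."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        d_all = sum(self.n_event[c] for c in self.n_event)
        d1 = self.n_event[cause]
        n_j = self.n_risk.astype(float)
        S_minus = np.concatenate([[1.0], self.surv[:-1]])
        F_j = self.cif[cause]
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(n_j > d_all, d_all / (n_j * (n_j - d_all)), 0.0)
        b = S_minus ** 2 * (n_j - d1) / n_j * d1 / n_j ** 2
        c = S_minus * d1 / n_j ** 2
        out = np.empty(len(t_arr))
        for i, tt in enumerate(t_arr):
            m = self.times <= tt
            Ft = self.cif_at(tt, cause)
            diff = Ft - F_j[m]
            out[i] = np.sum(diff ** 2 * a[m]) + np.sum(b[m]) \
                - 2.0 * np.sum(diff * c[m])
        out = np.clip(out, 0.0, None)
        return out if np.ndim(t) else float(out[0])


def aalen_johansen_arrays(time, cause, entry=None,
                          causes=EVENT_CAUSES) -> CIFEstimate:
    """Aalen–Johansen estimator from raw arrays.

    ``time``: outcome times; ``cause``: labels among ``causes`` or
    'censored'; ``entry``: optional left-truncation (delayed entry)
    times, with risk sets {i : entry_i < t <= time_i}.
    """
    time = np.asarray(time, dtype=float)
    cause = np.asarray(cause, dtype=object)
    n = len(time)
    if n == 0:
        raise ValueError("at least one subject required")
    if entry is not None:
        entry = np.asarray(entry, dtype=float)
        if np.any(entry >= time):
            raise ValueError("entry time must be strictly before outcome time")

    is_event = np.isin(cause, causes)
    ev_times = np.unique(time[is_event])
    k = len(ev_times)
    # risk set: subjects with time >= t (events before censorings at ties)
    order = np.sort(time)
    n_out_before = np.searchsorted(order, ev_times, side="left")
    n_risk = n - n_out_before
    if entry is not None:
        entry_sorted = np.sort(entry)
        n_not_in = len(entry) - np.searchsorted(entry_sorted, ev_times, side="left")
        n_risk = n_risk - n_not_in

    n_event = {}
    for c in causes:
        tc = time[cause == c]
        n_event[c] = (np.searchsorted(np.sort(tc), ev_times, side="right")
                      - np.searchsorted(np.sort(tc), ev_times, side="left"))
    d_all = sum(n_event.values()) if k else np.zeros(0, dtype=int)

    with np.errstate(divide="ignore", invalid="ignore"):
        haz = np.where(n_risk > 0, d_all / n_risk, 0.0)
    surv = np.cumprod(1.0 - haz)
    s_minus = np.concatenate([[1.0], surv[:-1]])
    cif = {}
    for c in causes:
        with np.errstate(divide="ignore", invalid="ignore"):
            jumps = np.where(n_risk > 0, s_minus * n_event[c] / n_risk, 0.0)
        cif[c] = np.cumsum(jumps)
    return CIFEstimate(times=ev_times, surv=surv, cif=cif,
                       n_risk=n_risk, n_event=n_event, n_subjects=n,
                       entry=entry)


def aalen_johansen(cohort: Cohort, cause: str = "cardiac",
                   truncation=None) -> CIFEstimate:
    """Aalen–Johansen estimate for a cohort (all causes estimated
    jointly; ``cause`` only records the primary cause of interest).
    ``truncation``: optional array of delayed-entry times."""
    if cause not in EVENT_CAUSES:
        raise ValueError(f"cause must be one of {EVENT_CAUSES}")
    df = cohort.df
    return aalen_johansen_arrays(df["T"].values, df["e"].values, entry=truncation)


def cif_confidence_interval(est: CIFEstimate, level: float = 0.95,
                            cause: str = "cardiac", at_times=None) -> pd.DataFrame:
    """Pointwise symmetric normal CIs for the CIF, truncated to [0, 1]."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    tt = est.times if at_times is None else np.atleast_1d(np.asarray(at_times, float))
    z = norm.ppf(0.5 + level / 2.0)
    f = np.atleast_1d(est.cif_at(tt, cause))
    se = np.sqrt(np.atleast_1d(est.variance_at(tt, cause)))
    return pd.DataFrame({
        "time": tt, "cif": f, "se": se,
        "lo": np.clip(f - z * se, 0.0, 1.0),
        "hi": np.clip(f + z * se, 0.0, 1.0),
    })


@dataclass
class StackedIncidence:
    """Stacked layers (death below, cardiac on top) and headline values."""

    table: pd.DataFrame
    at_years: pd.DataFrame
    estimate: CIFEstimate


def stacked_incidence(cohort: Cohort, report_years=(30.0, 50.0),
                      level: float = 0.95) -> StackedIncidence:
    """Stacked cumulative-incidence layers: CIF_death(t) and
    CIF_death(t) + CIF_cardiac(t); the gap to 1 is overall survival.
    Headline per-cause values with pointwise CIs at ``report_years``."""
    est = aalen_johansen(cohort)
    table = pd.DataFrame({
        "time": est.times,
        "cif_death": est.cif["death_other"],
        "cif_death_plus_cardiac": est.cif["death_other"] + est.cif["cardiac"],
        "surv": est.surv,
    })
    rows = []
    for cause in EVENT_CAUSES:
        ci = cif_confidence_interval(est, level=level, cause=cause,
                                     at_times=np.asarray(report_years, float))
        for _, r in ci.iterrows():
            rows.append({"cause": cause, "time": r["time"], "cif": r["cif"],
                         "se": r["se"], "lo": r["lo"], "hi": r["hi"]})
    return StackedIncidence(table=table, at_years=pd.DataFrame(rows), estimate=est)
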