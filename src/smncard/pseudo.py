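"""Jackknife pseudo-observations of the Aalen–Johansen cumulative
incidence at a grid of time points.

For subject i and grid time t,

    PV_i(t) = n * F_hat(t) - (n - 1) * F_hat^(-i)(t),

where F_hat is the Aalen–Johansen CIF of the cause of interest on the
full sample and F_hat^(-i) the same estimator with subject i left out.
With no censoring this reduces exactly to the event indicator
1(T_i <= t, e_i = cause); with censoring pseudo-values may fall outside
[0, 1] and are deliberately not clipped.

Subjects sharing an identical (time, cause) pair have identical
pseudo-values, so the leave-one-out estimator is recomputed once per
distinct observed pair rather than once per subject; this grouping is
exact, not an approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = ["PseudoValueMatrix", "pseudo_values", "pseudo_values_arrays"]


@dataclass
class PseudoValueMatrix:
    subject_ids: np.ndarray
    grid_times: np.ndarray
    values: np.ndarray       # (n_subjects, n_grid)
    cause: str
    landmark: float | None = None
    timescale: str | None = None

    def to_long(self) -> pd.DataFrame:
        n, m = self.values.shape
        return pd.DataFrame({
            "subject_id": np.repeat(self.subject_ids, m),
            "grid_time": np.tile(self.grid_times, n),
            "pseudo_value": self.values.ravel(),
        })


def _cif_at_grid(time: np.ndarray, code: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """AJ CIF of cause code 1 (codes: 0 censored, 1 cause, 2 competing)
    evaluated at grid times.  ``time`` need not be sorted."""
    order = np.argsort(time, kind="stable")
    ts, cs = time[order], code[order]
    n = len(ts)
    is_ev = cs > 0
    if not is_ev.any():
        return np.zeros(len(grid))
    ev_times = np.unique(ts[is_ev])
    n_risk = n - np.searchsorted(ts, ev_times, side="left")
    t_ev = ts[is_ev]
    d_all = (np.searchsorted(t_ev, ev_times, side="right")
             - np.searchsorted(t_ev, ev_times, side="left"))
    t_c1 = np.sort(ts[cs == 1])
    d1 = (np.searchsorted(t_c1, ev_times, side="right")
          - np.searchsorted(t_c1, ev_times, side="left"))
    haz = d_all / n_risk
    surv = np.cumprod(1.0 - haz)
    s_minus = np.concatenate([[1.0], surv[:-1]])
    F = np.cumsum(s_minus * d1 / n_risk)
    idx = np.searchsorted(ev_times, grid, side="right") - 1
    return np.where(idx >= 0, F[np.maximum(idx, 0)], 0.0)


def pseudo_values_arrays(time, cause_labels, grid, cause: str,
                         competing=("cardiac", "death_other"),
                         min_tail_events: int = 5) -> np.ndarray:
    """Pseudo-value matrix (subjects x grid) from raw arrays."""
    time = np.asarray(time, dtype=float)
    labels = np.asarray(cause_labels, dtype=object)
    grid = np.asarray(grid, dtype=float)
    n = len(time)
    if n < 2:
        raise ValueError("pseudo-values require at least 2 subjects")
    if len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-empty and strictly increasing")

    code = np.zeros(n, dtype=int)
    code[np.isin(labels, [c for c in competing if c != cause])] = 2
    code[labels == cause] = 1

    t_cause = time[code == 1]
    last_obs = time.max()
    if np.any(grid > last_obs):
        warnings.warn(
            f"grid extends beyond the last observed time {last_obs:.3g}; "
            "pseudo-values there are computed at the last observed time",
            stacklevel=2)
    if (t_cause < grid[0]).sum() < min_tail_events:
        warnings.warn(
            f"fewer than {min_tail_events} events of cause '{cause}' before "
            f"the first grid time {grid[0]:.3g}", stacklevel=2)
    if (t_cause > grid[-1]).sum() < min_tail_events:
        warnings.warn(
            f"fewer than {min_tail_events} events of cause '{cause}' after "
            f"the last grid time {grid[-1]:.3g}", stacklevel=2)

    F_full = _cif_at_grid(time, code, grid)
    # identical (time, cause) observations yield identical leave-one-out
    # estimates: compute once per distinct pair
    pairs = np.rec.fromarrays([time, code], names=["t", "c"])
    uniq, inverse = np.unique(pairs, return_inverse=True)
    loo = np.empty((len(uniq), len(grid)))
    keep = np.ones(n, dtype=bool)
    for k, pat in enumerate(uniq):
        i = int(np.argmax(inverse == k))
        keep[i] = False
        loo[k] = _cif_at_grid(time[keep], code[keep], grid)
        keep[i] = True
    return n * F_full[None, :] - (n - 1) * loo[inverse]


def pseudo_values(data, cause: str, grid, min_tail_events: int = 5) -> PseudoValueMatrix:
    """Jackknife pseudo-values of the AJ CIF for ``cause`` at ``grid``.

    ``data`` may be a :class:`~smncard.cohort.Cohort` (times on the
    since-diagnosis scale) or a :class:`~smncard.landmark.LandmarkDataset`
    (residual time since the landmark).
    """
    landmark = None
    timescale = None
    if isinstance(data, Cohort):
        df = data.df
        time = df["T"].values
        labels = df["e"].values
        ids = df["subject_id"].values
    else:  # LandmarkDataset
        df = data.df
        time = df["time"].values
        labels = df["cause"].values
        ids = df["subject_id"].values
        landmark = data.s
        timescale = data.timescale
    vals = pseudo_values_arrays(time, labels, grid, cause,
                                min_tail_events=min_tail_events)
    return PseudoValueMatrix(subject_ids=np.asarray(ids),
                             grid_times=np.asarray(grid, dtype=float),
                             values=vals, cause=cause,
                             landmark=landmark, timescale=timescale)
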