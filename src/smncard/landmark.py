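"""Landmark datasets: conditioning on event-free survival at time s.

To use SMN occurrence as an exposure without immortal-time bias, each
landmark dataset keeps only subjects event-free and under observation at
the landmark time s, freezes SMN status at s (``smn_time <= s``, closed
at s: an SMN diagnosed exactly at the landmark is known then) and
measures residual time from s.  Two time scales are supported: years
since childhood cancer diagnosis, and attained age (with delayed entry:
a subject only qualifies for an attained-age landmark if their cohort
entry age, age at diagnosis + 5, is at or below s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, ENTRY_TIME, SMN_TYPES

__all__ = ["LandmarkDataset", "build_landmark", "landmark_grid_report",
           "EXPOSURE_TYPE_LEVELS"]

TIMESCALES = ("since_diagnosis", "attained_age")
EXPOSURE_TYPE_LEVELS = tuple(t for t in SMN_TYPES if t != "none")


class EmptyLandmarkError(ValueError):
    """No subject is event-free and under observation at the landmark."""


@dataclass
class LandmarkDataset:
    """Subjects at risk at landmark ``s`` with exposure frozen at ``s``
    and residual outcome time (years after the landmark)."""

    s: float
    timescale: str
    exposure_mode: str
    df: pd.DataFrame  # subject_id, time (residual), cause, exposure*, covariates

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_exposed(self) -> int:
        return int((self.df["exposure"] == 1).sum())


def build_landmark(cohort: Cohort, s: float, timescale: str = "since_diagnosis",
                   exposure_mode: str = "binary") -> LandmarkDataset:
    """Landmark dataset at time ``s`` on the chosen time scale.

    since_diagnosis: include T > s; exposed iff smn_time <= s.
    attained_age: include subjects with entry age <= s (under observation
    at age s) and age at diagnosis + T > s; exposed iff the SMN occurred
    at or before age s.
    """
    if timescale not in TIMESCALES:
        raise ValueError(f"timescale must be one of {TIMESCALES}")
    if exposure_mode not in ("binary", "by_type"):
        raise ValueError("exposure_mode must be 'binary' or 'by_type'")
    df = cohort.df
    smn = df["smn_time"].values.astype(float)
    if timescale == "since_diagnosis":
        if s <= ENTRY_TIME:
            raise ValueError(f"landmark s must be > {ENTRY_TIME} on the "
                             "since-diagnosis scale")
        include = df["T"].values > s
        residual = df["T"].values - s
        exposed = np.nan_to_num(smn, nan=np.inf) <= s
    else:
        age_out = df["age_at_diagnosis"].values + df["T"].values
        age_entry = df["age_at_diagnosis"].values + ENTRY_TIME
        include = (age_entry <= s) & (age_out > s)
        residual = age_out - s
        age_smn = df["age_at_diagnosis"].values + np.nan_to_num(smn, nan=np.inf)
        exposed = age_smn <= s
    if not include.any():
        raise EmptyLandmarkError(
            f"no subjects at risk at landmark s={s} ({timescale})")

    out = df.loc[include].copy().reset_index(drop=True)
    out["time"] = residual[include]
    out["cause"] = out["e"]
    out["exposure"] = exposed[include].astype(int)
    if exposure_mode == "by_type":
        etype = np.where(out["exposure"] == 1, out["smn_type"], "no_smn")
        out["exposure_type"] = etype
    return LandmarkDataset(s=float(s), timescale=timescale,
                           exposure_mode=exposure_mode, df=out)


def landmark_grid_report(cohort: Cohort, landmarks) -> pd.DataFrame:
    """Inclusion/exposure/event counts per landmark.

    ``landmarks``: iterable of (s, timescale) pairs, or of bare s values
    (then taken on the since-diagnosis scale).
    """
    rows = []
    for lm in landmarks:
        s, timescale = lm if isinstance(lm, (tuple, list)) else (lm, "since_diagnosis")
        try:
            ds = build_landmark(cohort, s, timescale)
            rows.append({
                "timescale": timescale, "s": float(s),
                "n_included": len(ds), "n_exposed": ds.n_exposed,
                "cardiac_events": int((ds.df["cause"] == "cardiac").sum()),
                "deaths": int((ds.df["cause"] == "death_other").sum()),
            })
        except EmptyLandmarkError:
            rows.append({"timescale": timescale, "s": float(s),
                         "n_included": 0, "n_exposed": 0,
                         "cardiac_events": 0, "deaths": 0})
    return pd.DataFrame(rows)
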