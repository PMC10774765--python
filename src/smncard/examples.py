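"""Deterministic example cohorts.

:func:`fccss_reference_counts_cohort` builds a synthetic cohort whose
headline descriptive counts equal the published FCCSS cohort
description (7,670 five-year survivors; 4,201 female; 795 SMNs of which
90 breast cancers; 329 cardiac events without and 49 after an SMN; 194
heart-failure cases among the 378 cardiac events; 1,497 deaths; 1,257 +
1,144 survivors above 100 mg/m2 of anthracyclines).  Only these marginal
counts are reproduced — the joint distribution, times and the remaining
covariates are schematic — so the cohort is suitable for exercising the
descriptive operations, not for inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = ["fccss_reference_counts_cohort"]

N = 7670


def _fill(values, segments):
    """Assign segment labels by contiguous index blocks."""
    out = np.empty(N, dtype=object) if isinstance(segments[0][0], str) \
        else np.zeros(N, dtype=float)
    out[:] = values
    i = 0
    for val, count in segments:
        out[i:i + count] = val
        i += count
    return out


def fccss_reference_counts_cohort() -> Cohort:
    df = pd.DataFrame({"subject_id": [f"R{i:05d}" for i in range(N)]})
    df["sex"] = _fill("male", [("female", 4201)])
    df["age_at_diagnosis"] = _fill(16.0, [(3.0, 3726), (7.0, 1678), (12.0, 1623)])
    df["year_of_diagnosis"] = 1985

    # treatment combination blocks: neither 902 / RT alone 1088 /
    # chemo alone 2574 / RT and chemo 3106
    any_rt = np.zeros(N, dtype=int)
    any_rt[902:1990] = 1
    any_rt[4564:] = 1
    any_chemo = np.zeros(N, dtype=int)
    any_chemo[1990:] = 1
    df["any_rt"], df["any_chemo"] = any_rt, any_chemo

    # anthracycline dose categories: 5,060 zero / 209 in (0,100] /
    # 1,257 in (100,250] / 1,144 above 250 (all within chemo receivers)
    df["anthracycline_dose"] = _fill(0.0, [(0.0, 5060), (50.0, 209),
                                           (150.0, 1257), (300.0, 1144)])
    alk = np.zeros(N, dtype=int)
    alk[1990:5600] = 1          # 3,610 alkylating
    plat = np.zeros(N, dtype=int)
    plat[1990:3615] = 1         # 1,625 platinum
    df["alkylating"], df["platinum"] = alk, plat

    heart = np.zeros(N)
    heart[902:1990] = 2.0
    heart[4564:5825] = 2.0      # with the RT-alone block: 2,349 in (0,5]
    heart[5825:6398] = 10.0     # 573 in (5,15]
    heart[6398:7041] = 20.0     # 643 in (15,35]
    heart[7041:7133] = 40.0     # 92 above 35
    df["heart_rt_dose"] = heart
    df["brain_rt_dose"] = 0.0
    neck = np.zeros(N, dtype=int)
    neck[902:1990] = 1
    neck[4564:7146] = 1         # 3,670 neck RT in total
    df["neck_rt"] = neck

    # events: SMN subjects first (49 cardiac after SMN, rest censored),
    # then 329 cardiac without SMN, then 1,497 deaths, rest censored
    smn_time = np.full(N, np.nan)
    smn_time[:795] = 15.0
    smn_type = np.full(N, "none", dtype=object)
    smn_type[:90] = "breast_female"       # within the female block
    smn_type[90:160] = "sarcoma_bone_soft"
    smn_type[160:795] = "other_unknown"
    e = np.full(N, "censored", dtype=object)
    e[:49] = "cardiac"
    e[795:1124] = "cardiac"
    e[1124:2621] = "death_other"
    df["smn_time"], df["smn_type"] = smn_time, smn_type
    df["T"], df["e"] = 30.0, e

    subtype = np.full(N, "", dtype=object)
    cardiac_idx = np.concatenate([np.arange(49), np.arange(795, 1124)])
    shares = [("heart_failure", 194), ("valvular", 55), ("arrhythmia", 46),
              ("pericardial", 28), ("ischemic", 28), ("other", 27)]
    j = 0
    for label, count in shares:
        subtype[cardiac_idx[j:j + count]] = label
        j += count
    df["cardiac_subtype"] = subtype
    return Cohort.from_frame(df)
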