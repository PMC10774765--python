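"""Shared covariate-set design matrices for the regression stages.

Three nested adjustment sets mirror how much information a clinician may
have available:

* ``univariable`` — exposure only;
* ``binary_adjusted`` — exposure + sex, age at diagnosis (categories),
  diagnosis era (before/after 1980), plus radiotherapy (yes/no) and
  chemotherapy (yes/no);
* ``dose_adjusted`` — exposure + sex, age categories, era, alkylating
  agent, platinum agent, neck radiotherapy, and categorical cumulative
  anthracycline dose and mean heart/brain radiotherapy dose.

Categorical covariates are indicator-coded against the zero-dose (or
youngest-age) reference level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import (AGE_DX_LABELS, ANTHRACYCLINE_LABELS, BRAIN_RT_LABELS,
                     HEART_RT_LABELS)
from .landmark import EXPOSURE_TYPE_LEVELS

__all__ = ["COVARIATE_SETS", "build_design", "exposure_columns"]

COVARIATE_SETS = ("univariable", "binary_adjusted", "dose_adjusted")

_ADJUSTMENT_TOKENS = {
    "univariable": (),
    "binary_adjusted": ("female", "age_cat", "era_pre1980", "any_rt", "any_chemo"),
    "dose_adjusted": ("female", "age_cat", "era_pre1980", "alkylating",
                      "platinum", "neck_rt", "anthracycline_cat",
                      "heart_rt_cat", "brain_rt_cat"),
}

_CAT_SPECS = {
    "age_cat": ("age_at_diagnosis_cat", AGE_DX_LABELS),
    "anthracycline_cat": ("anthracycline_cat", ANTHRACYCLINE_LABELS),
    "heart_rt_cat": ("heart_rt_cat", HEART_RT_LABELS),
    "brain_rt_cat": ("brain_rt_cat", BRAIN_RT_LABELS),
}


def exposure_columns(df: pd.DataFrame, exposure_mode: str = "binary") -> pd.DataFrame:
    """Exposure regressors: a single SMN indicator, or one indicator per
    SMN type (reference: no SMN)."""
    if exposure_mode == "binary":
        return pd.DataFrame({"smn": df["exposure"].astype(float).values},
                            index=df.index)
    out = pd.DataFrame(index=df.index)
    for lev in EXPOSURE_TYPE_LEVELS:
        out[f"smn_{lev}"] = (df["exposure_type"] == lev).astype(float).values
    return out


def build_design(df: pd.DataFrame, covset: str,
                 exposure_mode: str = "binary") -> pd.DataFrame:
    """Design matrix (exposure first, no intercept column) for one
    covariate set on a landmark or episode table."""
    if covset not in COVARIATE_SETS:
        raise ValueError(f"covset must be one of {COVARIATE_SETS}")
    parts = [exposure_columns(df, exposure_mode)]
    adj = pd.DataFrame(index=df.index)
    for token in _ADJUSTMENT_TOKENS[covset]:
        if token == "female":
            adj["female"] = (df["sex"] == "female").astype(float).values
        elif token in _CAT_SPECS:
            col, labels = _CAT_SPECS[token]
            for lab in labels[1:]:  # first label is the reference
                adj[f"{col}[{lab}]"] = (df[col] == lab).astype(float).values
        else:
            adj[token] = df[token].astype(float).values
    parts.append(adj)
    return pd.concat(parts, axis=1)
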