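"""Subject-level cohort data model for 5-year childhood cancer survivors.

One row per survivor: demographics, childhood-cancer treatment exposures,
the time of a second malignant neoplasm (SMN) if one occurred, and a
right-censored time-to-first-event outcome ``T`` (years since childhood
cancer diagnosis) with cause label ``e`` in {cardiac, death_other,
censored}.  The SMN is an intermediate, non-terminating state: it may
precede (or coincide with) the terminating event but never ends follow-up
by itself.

The module validates the invariants of this data model, reads/writes it
as plain CSV (with an optional schema mapping for foreign column names),
and reproduces the standard descriptive summaries of such a cohort
(event tabulation, a "Table 1", median follow-up).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CAUSES",
    "SMN_TYPES",
    "SchemaError",
    "CohortValidationError",
    "SubjectRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "apply_five_year_exclusion",
    "tabulate_events",
    "EventTabulation",
    "table_one",
    "median_followup",
    "FollowupSummary",
    "percent",
    "dose_category",
]

CAUSES = ("cardiac", "death_other", "censored")
SMN_TYPES = ("none", "breast_female", "sarcoma_bone_soft", "other_unknown")

ENTRY_TIME = 5.0  # years since diagnosis at which survivors enter the cohort

# Dose/age category cut-points; dose intervals are closed on the right,
# e.g. anthracyclines 100 mg/m2 falls in "0-100".  Zero dose is its own
# category.  Age-at-diagnosis intervals are closed on the left (<5 means
# [0,5)), matching how ages are conventionally banded.
ANTHRACYCLINE_EDGES = (0.0, 100.0, 250.0, np.inf)
ANTHRACYCLINE_LABELS = ("0", "0-100", "100-250", ">250")
HEART_RT_EDGES = (0.0, 5.0, 15.0, 35.0, np.inf)
HEART_RT_LABELS = ("0", "0-5", "5-15", "15-35", ">35")
BRAIN_RT_EDGES = (0.0, 20.0, 30.0, 50.0, np.inf)
BRAIN_RT_LABELS = ("0", "0-20", "20-30", "30-50", ">50")
AGE_DX_EDGES = (5.0, 10.0, 15.0)
AGE_DX_LABELS = ("<5", "5-10", "10-15", ">15")

REQUIRED_COLUMNS = (
    "subject_id",
    "sex",
    "age_at_diagnosis",
    "year_of_diagnosis",
    "any_chemo",
    "any_rt",
    "anthracycline_dose",
    "alkylating",
    "platinum",
    "heart_rt_dose",
    "brain_rt_dose",
    "neck_rt",
    "smn_time",
    "smn_type",
    "T",
    "e",
)

DERIVED_COLUMNS = (
    "era_pre1980",
    "anthracycline_cat",
    "heart_rt_cat",
    "brain_rt_cat",
    "age_at_diagnosis_cat",
)


class SchemaError(ValueError):
    """A required column is missing or the schema mapping is malformed."""


class CohortValidationError(ValueError):
    """A subject violates a data-model invariant; names subject and rule."""


def dose_category(values, edges: Sequence[float], labels: Sequence[str]) -> np.ndarray:
    """Categorise continuous nonnegative doses; 0 is its own category and
    the positive intervals are half-open, closed on the right."""
    v = np.asarray(values, dtype=float)
    out = np.empty(v.shape, dtype=object)
    inner = np.asarray(edges[1:-1], dtype=float)
    idx = np.searchsorted(inner, v, side="left")
    for k, lab in enumerate(labels[1:]):
        out[idx == k] = lab
    out[v == 0] = labels[0]
    if np.any(v < 0) or np.any(~np.isfinite(v)):
        raise CohortValidationError("doses must be finite and >= 0")
    return out


def age_category(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    idx = np.searchsorted(np.asarray(AGE_DX_EDGES), v, side="right")
    return np.asarray(AGE_DX_LABELS, dtype=object)[idx]


def percent(count: float, denom: float, decimals: int = 1) -> float:
    """Percentage with round-half-away-from-zero at ``decimals``."""
    if denom == 0:
        return float("nan")
    x = 100.0 * count / denom
    scale = 10.0 ** decimals
    return float(np.sign(x) * np.floor(abs(x) * scale + 0.5) / scale)


@dataclass
class SubjectRecord:
    """One survivor; convenience constructor for toy cohorts and tests."""

    subject_id: str
    sex: str = "female"
    age_at_diagnosis: float = 5.0
    year_of_diagnosis: int = 1985
    any_chemo: int = 0
    any_rt: int = 0
    anthracycline_dose: float = 0.0
    alkylating: int = 0
    platinum: int = 0
    heart_rt_dose: float = 0.0
    brain_rt_dose: float = 0.0
    neck_rt: int = 0
    smn_time: float | None = None
    smn_type: str = "none"
    T: float = 30.0
    e: str = "censored"

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        if d["smn_time"] is None:
            d["smn_time"] = np.nan
        return d


@dataclass
class Cohort:
    """A validated collection of survivors with time origin at childhood
    cancer diagnosis."""

    df: pd.DataFrame
    time_origin: str = "diagnosis"

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, validate: bool = True) -> "Cohort":
        df = _coerce(df.copy())
        df = _derive(df)
        if validate:
            _validate(df)
        return cls(df=df.reset_index(drop=True))

    @classmethod
    def from_records(cls, records: Iterable[SubjectRecord]) -> "Cohort":
        rows = [r.as_dict() for r in records]
        if not rows:
            raise CohortValidationError("cohort must be non-empty")
        return cls.from_frame(pd.DataFrame(rows))

    def write(self, path) -> None:
        write_cohort(self, path)


def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df["subject_id"] = df["subject_id"].astype(str)
    for c in ("age_at_diagnosis", "anthracycline_dose", "heart_rt_dose",
              "brain_rt_dose", "smn_time", "T"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["year_of_diagnosis"] = pd.to_numeric(df["year_of_diagnosis"]).astype(int)
    for c in ("any_chemo", "any_rt", "alkylating", "platinum", "neck_rt"):
        df[c] = pd.to_numeric(df[c]).astype(int)
    df["sex"] = df["sex"].astype(str)
    df["e"] = df["e"].astype(str)
    df["smn_type"] = df["smn_type"].fillna("none").astype(str)
    return df


def _derive(df: pd.DataFrame) -> pd.DataFrame:
    declared = {c: df[c].copy() for c in DERIVED_COLUMNS if c in df.columns}
    df["era_pre1980"] = (df["year_of_diagnosis"] < 1980).astype(int)
    df["anthracycline_cat"] = dose_category(
        df["anthracycline_dose"], ANTHRACYCLINE_EDGES, ANTHRACYCLINE_LABELS)
    df["heart_rt_cat"] = dose_category(
        df["heart_rt_dose"], HEART_RT_EDGES, HEART_RT_LABELS)
    df["brain_rt_cat"] = dose_category(
        df["brain_rt_dose"], BRAIN_RT_EDGES, BRAIN_RT_LABELS)
    df["age_at_diagnosis_cat"] = age_category(df["age_at_diagnosis"])
    for c, declared_vals in declared.items():
        mismatch = declared_vals.astype(str).values != df[c].astype(str).values
        if mismatch.any():
            sid = df.loc[np.flatnonzero(mismatch)[0], "subject_id"]
            raise CohortValidationError(
                f"subject {sid}: declared {c} inconsistent with continuous value")
    return df


def _validate(df: pd.DataFrame) -> None:
    if len(df) == 0:
        raise CohortValidationError("cohort must be non-empty")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise CohortValidationError(f"duplicate subject_id: {dup.iloc[0]}")

    def bad(mask, rule):
        if np.asarray(mask).any():
            sid = df.loc[np.flatnonzero(np.asarray(mask))[0], "subject_id"]
            raise CohortValidationError(f"subject {sid}: {rule}")

    bad(~df["sex"].isin(["female", "male"]), "sex must be 'female' or 'male'")
    bad(~df["e"].isin(CAUSES), f"e must be one of {CAUSES}")
    bad(~df["smn_type"].isin(SMN_TYPES), f"smn_type must be one of {SMN_TYPES}")
    bad(~np.isfinite(df["T"]) | (df["T"] <= 0), "T must be finite and > 0")
    bad(df["age_at_diagnosis"] < 0, "age_at_diagnosis must be >= 0")

    has_smn = df["smn_time"].notna().values
    bad(has_smn & (df["smn_time"] < ENTRY_TIME).values,
        f"smn_time must be >= {ENTRY_TIME} (years since diagnosis)")
    bad(has_smn & (df["smn_time"] > df["T"]).values,
        "smn_time must be <= T (SMN precedes or coincides with the terminating event)")
    bad(has_smn != (df["smn_type"] != "none").values,
        "smn_type must be 'none' exactly when smn_time is absent")
    bad((df["smn_type"] == "breast_female").values & (df["sex"] != "female").values,
        "smn_type 'breast_female' requires sex 'female'")


def _load_schema(schema_config) -> Mapping[str, str] | None:
    if schema_config is None:
        return None
    if isinstance(schema_config, Mapping):
        return dict(schema_config)
    path = Path(schema_config)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_cohort(path, schema_config=None) -> Cohort:
    """Read a cohort CSV; ``schema_config`` (dict or YAML/JSON file) maps
    canonical field names onto the file's column names."""
    df = pd.read_csv(path)
    mapping = _load_schema(schema_config)
    if mapping:
        rename = {src: canon for canon, src in mapping.items() if src in df.columns}
        absent = [src for canon, src in mapping.items() if src not in df.columns]
        if absent:
            raise SchemaError(f"mapped column(s) not in file: {', '.join(absent)}")
        df = df.rename(columns=rename)
    return Cohort.from_frame(df)


def write_cohort(cohort: Cohort, path) -> None:
    cols = list(REQUIRED_COLUMNS) + list(DERIVED_COLUMNS)
    cohort.df.to_csv(path, index=False, columns=cols)


def apply_five_year_exclusion(cohort: Cohort) -> tuple[Cohort, int]:
    """Drop subjects who are not 5-year survivors: any first event before
    5 years since diagnosis, a terminating event at exactly 5 years, or
    censoring before 5 years.  Returns the retained cohort and the number
    excluded."""
    df = cohort.df
    drop = (df["T"] < ENTRY_TIME) | (
        (df["T"] == ENTRY_TIME) & (df["e"] != "censored"))
    kept = df.loc[~drop]
    n_excluded = int(drop.sum())
    if len(kept) == 0:
        return Cohort(df=kept.reset_index(drop=True)), n_excluded
    return Cohort.from_frame(kept), n_excluded


@dataclass
class EventTabulation:
    n: int
    n_smn: int
    cardiac_without_smn: int
    cardiac_after_smn: int
    cardiac_total: int
    deaths: int
    smn_type_breakdown: pd.DataFrame
    cardiac_subtype_breakdown: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"quantity": ["n", "n_smn", "cardiac_without_smn",
                          "cardiac_after_smn", "cardiac_total", "deaths"],
             "count": [self.n, self.n_smn, self.cardiac_without_smn,
                       self.cardiac_after_smn, self.cardiac_total, self.deaths]})


def _breakdown(labels: pd.Series, order: Sequence[str] | None = None) -> pd.DataFrame:
    counts = labels.value_counts()
    if order is not None:
        counts = counts.reindex([c for c in order if c in counts.index])
    total = int(counts.sum())
    return pd.DataFrame({
        "category": counts.index,
        "count": counts.values.astype(int),
        "pct": [percent(c, total) for c in counts.values],
    })


def tabulate_events(cohort: Cohort, cardiac_subtype: str | None = None) -> EventTabulation:
    """Counts of SMNs, cardiac events with/without a prior SMN, deaths;
    percentage breakdowns of SMN types and (optionally, if a subtype
    column is present) cardiac-disease subtypes."""
    df = cohort.df
    has_smn = df["smn_time"].notna()
    cardiac = df["e"] == "cardiac"
    n_smn = int(has_smn.sum())
    with_smn = int((cardiac & has_smn).sum())
    without_smn = int((cardiac & ~has_smn).sum())
    deaths = int((df["e"] == "death_other").sum())
    smn_bd = _breakdown(df.loc[has_smn, "smn_type"],
                        order=[t for t in SMN_TYPES if t != "none"])
    sub_bd = None
    if cardiac_subtype is not None:
        if cardiac_subtype not in df.columns:
            raise SchemaError(f"cardiac subtype column '{cardiac_subtype}' not found")
        sub_bd = _breakdown(df.loc[cardiac, cardiac_subtype])
    return EventTabulation(
        n=len(df), n_smn=n_smn, cardiac_without_smn=without_smn,
        cardiac_after_smn=with_smn, cardiac_total=without_smn + with_smn,
        deaths=deaths, smn_type_breakdown=smn_bd,
        cardiac_subtype_breakdown=sub_bd)


_TABLE_ONE_VARS = (
    ("sex", ("female", "male")),
    ("age_at_diagnosis_cat", AGE_DX_LABELS),
    ("deceased", ("no", "yes")),
    ("treatment_combination",
     ("neither", "rt_alone", "chemo_alone", "rt_and_chemo")),
    ("anthracycline_cat", ANTHRACYCLINE_LABELS),
    ("alkylating", ("0", "1")),
    ("platinum", ("0", "1")),
    ("heart_rt_cat", HEART_RT_LABELS),
    ("brain_rt_cat", BRAIN_RT_LABELS),
    ("neck_rt", ("0", "1")),
    ("era_pre1980", ("0", "1")),
)


def table_one(cohort: Cohort) -> pd.DataFrame:
    """Per-category counts and percentages of cohort size (one decimal),
    including the radiotherapy/chemotherapy cross-classification."""
    df = cohort.df.copy()
    df["deceased"] = np.where(df["e"] == "death_other", "yes", "no")
    combo = np.select(
        [(df["any_rt"] == 0) & (df["any_chemo"] == 0),
         (df["any_rt"] == 1) & (df["any_chemo"] == 0),
         (df["any_rt"] == 0) & (df["any_chemo"] == 1)],
        ["neither", "rt_alone", "chemo_alone"], default="rt_and_chemo")
    df["treatment_combination"] = combo
    n = len(df)
    rows = []
    for var, cats in _TABLE_ONE_VARS:
        vals = df[var].astype(str)
        for cat in cats:
            cnt = int((vals == cat).sum())
            rows.append({"variable": var, "category": cat,
                         "count": cnt, "pct": percent(cnt, n)})
    return pd.DataFrame(rows)


@dataclass
class FollowupSummary:
    median: float
    q1: float
    q3: float


def median_followup(cohort: Cohort) -> FollowupSummary:
    """Median and IQR of the outcome time T over all subjects (events and
    censored alike), with linear interpolation between order statistics."""
    if len(cohort) == 0:
        raise CohortValidationError("cohort must be non-empty")
    t = np.asarray(cohort.df["T"], dtype=float)
    q1, med, q3 = np.percentile(t, [25, 50, 75])
    return FollowupSummary(median=float(med), q1=float(q1), q3=float(q3))
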