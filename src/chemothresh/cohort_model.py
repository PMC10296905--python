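"""Cohort data model, CSV I/O, eligibility filtering and descriptive summaries.

A cohort is held as a :class:`pandas.DataFrame` with one row per patient and
a fixed column schema (see :data:`COLUMNS`).  Follow-up time is measured in
whole months, as cancer registries report it; the outcome event is death
from breast cancer (breast-cancer-specific survival), with all other exits
treated as censoring.

The Oncotype DX recurrence score (RS, an integer 0-100) is classified into
the registry's three risk categories: low (RS < 18), intermediate
(18 <= RS <= 30) and high (RS > 30).  Both boundary scores fall in the
intermediate category; this is the only reading under which the three
categories partition [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

#: Cohort CSV column names, in order.
COLUMNS = [
    "id", "age", "race", "stage", "grade", "er_status", "pr_status",
    "subtype", "ln_status", "rs", "chemo", "time_months", "event",
]

RACES = frozenset({"white", "black", "asian", "other"})
STAGES = frozenset({"I", "II", "III", "IV"})
GRADES = frozenset({"well", "moderate", "poor", "undifferentiated"})
RECEPTOR_STATUSES = frozenset({"positive", "negative"})
SUBTYPES = frozenset({"luminalA", "luminalB", "pre2010"})
LN_STATUSES = frozenset({"negative", "positive"})
CHEMO_LEVELS = frozenset({"yes", "no_unknown"})
EVENT_LEVELS = frozenset({"bcss_death", "censored"})

_CATEGORY_DOMAINS = {
    "race": RACES,
    "stage": STAGES,
    "grade": GRADES,
    "er_status": RECEPTOR_STATUSES,
    "pr_status": RECEPTOR_STATUSES,
    "subtype": SUBTYPES,
    "ln_status": LN_STATUSES,
    "chemo": CHEMO_LEVELS,
    "event": EVENT_LEVELS,
}

#: Registry risk-category boundaries on the recurrence score.
RS_LOW_UPPER = 18     # rs < 18 -> low
RS_HIGH_LOWER = 30    # rs > 30 -> high


class SchemaError(ValueError):
    """Cohort file does not match the documented column schema."""


class EmptyCohortError(ValueError):
    """Cohort file contains no patient rows."""


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV into a typed DataFrame.

    Raises :class:`SchemaError` naming the first missing required column and
    :class:`EmptyCohortError` on a file without data rows.  Category values
    outside their enumeration raise a :class:`ValueError` listing the
    offending rows.  A blank ``rs`` field is preserved as missing (NaN).
    """
    df = pd.read_csv(path, dtype={"id": str})
    for col in COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cohort file is missing required column {col!r}")
    if len(df) == 0:
        raise EmptyCohortError(f"cohort file {path!r} has no patient rows")
    df = df[COLUMNS].copy()
    df["age"] = df["age"].astype(float)
    df["rs"] = pd.to_numeric(df["rs"], errors="coerce").astype(float)
    df["time_months"] = df["time_months"].astype(float)
    bad_rows: list[str] = []
    for col, domain in _CATEGORY_DOMAINS.items():
        df[col] = df[col].astype(str)
        invalid = ~df[col].isin(domain)
        if invalid.any():
            idx = list(df.index[invalid][:10])
            bad_rows.append(f"{col}: rows {idx} contain values outside {sorted(domain)}")
    if bad_rows:
        raise ValueError("unparseable category values:\n" + "\n".join(bad_rows))
    if (df["time_months"] <= 0).any():
        raise ValueError("time_months must be positive for every patient")
    rs_bad = df["rs"].notna() & ((df["rs"] < 0) | (df["rs"] > 100))
    if rs_bad.any():
        raise ValueError(f"rs outside [0, 100] in rows {list(df.index[rs_bad][:10])}")
    if df["id"].duplicated().any():
        raise ValueError("patient ids are not unique")
    df.attrs["source"] = str(path)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to CSV (comma-separated, UTF-8, header row, blanks for missing)."""
    cohort[COLUMNS].to_csv(path, index=False)


@dataclass(frozen=True)
class EligibilityCriteria:
    """Row filter for the analysis cohort.

    The default criteria select the study population: ER-positive, stage I/II,
    luminal A (HR+/HER2-), ages 35-80 inclusive, with an available recurrence
    score, restricted to the three analysed race groups.
    """

    stages_allowed: frozenset = frozenset({"I", "II"})
    er_required: bool = True
    subtype_required: frozenset = frozenset({"luminalA"})
    age_min: float = 35.0
    age_max: float = 80.0
    ln_status_required: str = "negative"
    rs_required: bool = True
    races_allowed: frozenset = frozenset({"white", "black", "asian"})

    def __post_init__(self):
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be strictly less than age_max")


#: Named eligibility presets for the two analysed cohorts.
PRESETS = {
    "ln_neg": EligibilityCriteria(ln_status_required="negative"),
    "ln_pos": EligibilityCriteria(ln_status_required="positive"),
}


def apply_eligibility(cohort: pd.DataFrame, criteria: EligibilityCriteria) -> pd.DataFrame:
    """Return the rows satisfying every criterion, preserving input order.

    Idempotent; may return an empty frame.  Age bounds are inclusive at both
    ends.
    """
    keep = cohort["stage"].isin(criteria.stages_allowed)
    if criteria.er_required:
        keep &= cohort["er_status"] == "positive"
    keep &= cohort["subtype"].isin(criteria.subtype_required)
    keep &= (cohort["age"] >= criteria.age_min) & (cohort["age"] <= criteria.age_max)
    keep &= cohort["ln_status"] == criteria.ln_status_required
    if criteria.rs_required:
        keep &= cohort["rs"].notna()
    keep &= cohort["race"].isin(criteria.races_allowed)
    out = cohort.loc[keep].copy()
    out.attrs.update(cohort.attrs)
    return out


def classify_risk(rs) -> str | None:
    """Map a recurrence score to its registry risk category.

    rs < 18 -> ``"low"``; 18 <= rs <= 30 -> ``"intermediate"``;
    rs > 30 -> ``"high"``.  Missing rs returns ``None``.
    """
    if rs is None or (isinstance(rs, float) and np.isnan(rs)):
        return None
    if not 0 <= rs <= 100:
        raise ValueError(f"rs must lie in [0, 100], got {rs}")
    if rs < RS_LOW_UPPER:
        return "low"
    if rs <= RS_HIGH_LOWER:
        return "intermediate"
    return "high"


def risk_category_column(cohort: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_risk` over a cohort; missing rs -> NaN."""
    rs = cohort["rs"]
    cat = pd.Series(np.nan, index=cohort.index, dtype=object)
    cat[rs < RS_LOW_UPPER] = "low"
    cat[(rs >= RS_LOW_UPPER) & (rs <= RS_HIGH_LOWER)] = "intermediate"
    cat[rs > RS_HIGH_LOWER] = "high"
    return cat


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Descriptive summary per race and overall.

    Columns: n, pct_low / pct_intermediate / pct_high (risk-category shares
    among patients with a score), pct_pr_positive, pct_chemo, rs_mean,
    rs_median.  Chemotherapy percentages count the ``yes`` level only; the
    ``no_unknown`` level conflates untreated and unreported treatment.
    """
    if len(cohort) == 0:
        raise EmptyCohortError("cannot summarize an empty cohort")
    cat = risk_category_column(cohort)

    def one(group: pd.DataFrame, label: str) -> dict:
        g_cat = cat.loc[group.index].dropna()
        n_cat = len(g_cat)
        return {
            "group": label,
            "n": len(group),
            "pct_low": 100.0 * (g_cat == "low").sum() / n_cat if n_cat else np.nan,
            "pct_intermediate": 100.0 * (g_cat == "intermediate").sum() / n_cat if n_cat else np.nan,
            "pct_high": 100.0 * (g_cat == "high").sum() / n_cat if n_cat else np.nan,
            "pct_pr_positive": 100.0 * (group["pr_status"] == "positive").mean(),
            "pct_chemo": 100.0 * (group["chemo"] == "yes").mean(),
            "rs_mean": group["rs"].mean(),
            "rs_median": group["rs"].median(),
        }

    rows = [one(cohort, "overall")]
    for race, group in cohort.groupby("race", sort=True):
        rows.append(one(group, race))
    return pd.DataFrame(rows)
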