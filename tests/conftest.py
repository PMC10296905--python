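"""Shared fixtures: worked small datasets and helpers for building cohorts."""

import numpy as np
import pandas as pd
import pytest

from chemothresh.cohort_model import COLUMNS
from chemothresh.pipeline import make_fixtures

_BASE_ROW = {
    "stage": "I", "grade": "moderate", "er_status": "positive",
    "pr_status": "positive", "subtype": "luminalA", "ln_status": "negative",
    "race": "white", "age": 60.0, "rs": 20.0, "chemo": "no_unknown",
    "event": "bcss_death",
}


def build_cohort(rows) -> pd.DataFrame:
    """Cohort frame from per-row overrides of an eligible baseline patient."""
    recs = []
    for i, row in enumerate(rows):
        rec = dict(_BASE_ROW)
        rec["id"] = f"T{i:04d}"
        rec.update(row)
        recs.append(rec)
    return pd.DataFrame(recs)[COLUMNS]


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """The worked datasets written by the pipeline's fixture generator."""
    out = tmp_path_factory.mktemp("fixtures")
    return make_fixtures(out, seed=0)


@pytest.fixture()
def cox8_cohort():
    """8 patients, times 1..8 months, all events, binary treatment covariate."""
    return build_cohort([
        {"time_months": float(t), "chemo": "yes" if t % 2 == 0 else "no_unknown"}
        for t in range(1, 9)])


@pytest.fixture()
def na3_cohort():
    """3 patients, all dying at months 1, 2, 3 (Nelson-Aalen worked example)."""
    return build_cohort([{"time_months": float(t)} for t in (1, 2, 3)])


@pytest.fixture()
def fold5_cohort():
    """5 patients with recurrence scores 10, 20, 26, 31, 35."""
    return build_cohort([{"time_months": 10.0, "rs": float(r)}
                         for r in (10, 20, 26, 31, 35)])
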