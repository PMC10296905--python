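"""Cox proportional-hazards fits, concordance, stratified chemo HRs, rank tests.

Model fitting is delegated to :mod:`lifelines` (Efron tie correction, Wald
confidence intervals); this module owns the cohort-schema-aware design
matrix, the reference-level conventions of the analysis (low risk category,
white race, well-differentiated grade, stage I, chemotherapy ``no_unknown``),
and the stratified treatment-effect tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.utils import concordance_index as _ll_concordance
from scipy import stats

from .cohort_model import risk_category_column

#: Reference level for each categorical covariate (dropped from the design).
REFERENCE_LEVELS = {
    "risk_category": "low",
    "race": "white",
    "grade": "well",
    "stage": "I",
    "chemo": "no_unknown",
    "ln_status": "negative",
    "subtype": "luminalA",
    "er_status": "negative",
    "pr_status": "negative",
    "event": None,
}

_NUMERIC_COVARIATES = {"age", "rs", "time_months"}


class CoxFitError(RuntimeError):
    """Cox model failed to converge or the design is degenerate."""


@dataclass
class CoxFit:
    """A fitted Cox model: coefficient table, concordance and design recipe.

    ``table`` columns: term, level, coef, se, HR, ci_low, ci_high, p, n.
    HR = exp(coef); the 95% CI is exp(coef +- 1.96*se).
    """

    table: pd.DataFrame
    concordance: float
    n: int
    n_events: int
    covariates: tuple
    design_columns: tuple
    _fitter: CoxPHFitter

    def linear_predictor(self, cohort: pd.DataFrame) -> np.ndarray:
        """Log partial hazard for each row of ``cohort`` under this fit."""
        X = make_design(cohort, list(self.covariates))
        X = X.reindex(columns=list(self.design_columns), fill_value=0.0)
        coef = self._fitter.params_.reindex(list(self.design_columns)).to_numpy()
        return X.to_numpy(dtype=float) @ coef


def make_design(cohort: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Expand covariates into a numeric design matrix.

    Categorical covariates become indicator columns ``<name>[<level>]`` with
    the declared reference level dropped; ``risk_category`` is derived from
    the recurrence score on the fly.  Numeric covariates pass through.
    """
    pieces = []
    for cov in covariates:
        if cov == "risk_category":
            values = risk_category_column(cohort)
        elif cov in cohort.columns:
            values = cohort[cov]
        else:
            raise KeyError(f"covariate {cov!r} not present in cohort")
        if cov in _NUMERIC_COVARIATES:
            pieces.append(values.astype(float).rename(cov))
            continue
        ref = REFERENCE_LEVELS.get(cov)
        levels = [lv for lv in sorted(values.dropna().unique()) if lv != ref]
        for lv in levels:
            pieces.append((values == lv).astype(float).rename(f"{cov}[{lv}]"))
    X = pd.concat(pieces, axis=1)
    X.index = cohort.index
    return X


def fit_cox(cohort: pd.DataFrame, covariates: list[str]) -> CoxFit:
    """Fit a Cox proportional-hazards model of BCSS on the given covariates.

    Uses the Efron approximation for tied event times and Wald 95% intervals.
    Requires at least two events.  Non-convergence (including complete
    separation) raises :class:`CoxFitError` with the solver diagnostic.
    """
    events = (cohort["event"] == "bcss_death").astype(int)
    if events.sum() < 2:
        raise CoxFitError("need at least 2 events to fit a Cox model")
    X = make_design(cohort, covariates)
    frame = X.copy()
    frame["_time"] = cohort["time_months"].astype(float).to_numpy()
    frame["_event"] = events.to_numpy()
    frame = frame.dropna()
    fitter = CoxPHFitter()
    try:
        fitter.fit(frame, duration_col="_time", event_col="_event")
    except ConvergenceError as exc:  # includes complete-separation diagnostics
        raise CoxFitError(f"Cox model failed to converge: {exc}") from exc

    rows = []
    for col in X.columns:
        coef = fitter.params_[col]
        se = fitter.standard_errors_[col]
        term, level = (col.split("[", 1) + [""])[:2]
        rows.append({
            "term": term,
            "level": level.rstrip("]"),
            "coef": coef,
            "se": se,
            "HR": np.exp(coef),
            "ci_low": np.exp(coef - 1.96 * se),
            "ci_high": np.exp(coef + 1.96 * se),
            "p": fitter.summary.loc[col, "p"],
            "n": int(len(frame)),
        })
    return CoxFit(
        table=pd.DataFrame(rows),
        concordance=float(fitter.concordance_index_),
        n=int(len(frame)),
        n_events=int(frame["_event"].sum()),
        covariates=tuple(covariates),
        design_columns=tuple(X.columns),
        _fitter=fitter,
    )


def harrell_c(times, events, risks) -> float:
    """Harrell's concordance for arbitrary risk scores.

    Among usable pairs (the shorter observed time ends in an event), the
    fraction where the higher risk fails first; risk ties count 1/2.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    risks = np.asarray(risks, dtype=float)
    if events.sum() == 0 or len(times) < 2:
        raise ValueError("concordance undefined: no usable pairs")
    # lifelines expects higher score -> longer survival, hence the sign flip.
    return float(_ll_concordance(times, -risks, events))


def concordance_index(fit: CoxFit, cohort: pd.DataFrame) -> float:
    """Harrell's C of the fitted model's risk score on a cohort."""
    return harrell_c(cohort["time_months"].to_numpy(dtype=float),
                     (cohort["event"] == "bcss_death").astype(int).to_numpy(),
                     fit.linear_predictor(cohort))


_NOT_ESTIMABLE = {"coef": np.nan, "se": np.nan, "HR": np.nan,
                  "ci_low": np.nan, "ci_high": np.nan, "p": np.nan}


def chemo_hr_by_group(cohort: pd.DataFrame, race_subset: str | None = None) -> pd.DataFrame:
    """Univariate chemotherapy hazard ratio within each risk-category stratum.

    Returns one row per stratum with HR, 95% CI, n, n_events and an
    ``estimable`` flag.  A stratum is not estimable when either chemotherapy
    arm has fewer than two events; such strata are flagged rather than
    raising.
    """
    data = cohort if race_subset is None else cohort[cohort["race"] == race_subset]
    cat = risk_category_column(data)
    rows = []
    for stratum in ("low", "intermediate", "high"):
        sub = data[cat == stratum]
        row = {"stratum": stratum, "race": race_subset or "all",
               "n": int(len(sub)),
               "n_events": int((sub["event"] == "bcss_death").sum())}
        arm_events = sub.groupby("chemo")["event"].apply(lambda s: (s == "bcss_death").sum())
        ok = (len(sub) > 0
              and set(arm_events.index) == {"yes", "no_unknown"}
              and (arm_events >= 2).all())
        if ok:
            try:
                fit = fit_cox(sub, ["chemo"])
                row.update(fit.table.iloc[0][["coef", "se", "HR", "ci_low", "ci_high", "p"]])
                row["estimable"] = True
            except CoxFitError:
                row.update(_NOT_ESTIMABLE)
                row["estimable"] = False
        else:
            row.update(_NOT_ESTIMABLE)
            row["estimable"] = False
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    pvalue: float


def rank_test(sample_a, sample_b, paired: bool = False) -> RankTestResult:
    """Two-sided rank test between two samples.

    Unpaired samples (the default) use the Mann-Whitney U test: the exact
    null distribution when both samples have at most 12 observations and no
    ties are present, otherwise the normal approximation with tie
    correction.  ``paired=True`` runs the Wilcoxon signed-rank test on
    element-wise pairs.  Identical samples return p = 1 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length samples")
        if np.array_equal(a, b):
            return RankTestResult(statistic=0.0, pvalue=1.0)
        res = stats.wilcoxon(a, b, alternative="two-sided")
        return RankTestResult(statistic=float(res.statistic), pvalue=float(res.pvalue))
    if len(np.unique(np.concatenate([a, b]))) == 1:
        return RankTestResult(statistic=float(len(a) * len(b) / 2.0), pvalue=1.0)
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 12 and len(b) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankTestResult(statistic=float(res.statistic), pvalue=float(min(1.0, res.pvalue)))
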