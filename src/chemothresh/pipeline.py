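"""End-to-end analysis orchestration and test-fixture generation.

:func:`run_full_analysis` executes the whole pipeline in order — load or
generate a cohort, apply eligibility, descriptive summaries, Cox hazard
ratios and concordance with/without the risk classification, risk-stratified
chemotherapy hazard ratios, between-race score comparisons, the
counterfactual-forest benefit threshold with its subsample bootstrap,
per-race thresholds when every race subset is large enough, and fold
changes against the guideline cutoffs — logging stage boundaries and seeds.
A stage failure marks the report partial (naming the stage) and skips the
stages downstream of it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_model import (PRESETS, EligibilityCriteria, apply_eligibility,
                           read_cohort, summarize_cohort, write_cohort)
from .rsf_counterfactual import RSFConfig
from .survival_stats import chemo_hr_by_group, concordance_index, fit_cox, rank_test
from .synthetic_cohort import GroundTruth, SyntheticConfig, generate_cohort
from .threshold_estimation import (DEFAULT_PERSISTENCE, DEFAULT_SPAN,
                                   bootstrap_thresholds, estimate_threshold,
                                   fold_change, race_specific_thresholds)

logger = logging.getLogger("chemothresh")

DEFAULT_COVARIATES = ("age", "race", "stage", "grade", "risk_category", "chemo")
GUIDELINE_CUTOFFS = (25.0, 30.0)


@dataclass
class AnalysisConfig:
    """One config object driving a full run; round-trips through JSON/YAML."""

    generator: SyntheticConfig | None = None
    input_path: str | None = None
    preset: str = "ln_neg"
    covariates: tuple = DEFAULT_COVARIATES
    rsf: RSFConfig = field(default_factory=RSFConfig)
    n_iter: int = 10
    subsample_fraction: float = 0.70
    span: float = DEFAULT_SPAN
    persistence: int = DEFAULT_PERSISTENCE
    guideline_cutoffs: tuple = GUIDELINE_CUTOFFS
    min_race_n: int = 500
    by_race: bool = True
    master_seed: int = 0

    def __post_init__(self):
        if self.generator is None and self.input_path is None:
            raise ValueError("config needs either a generator block or an input_path")
        if self.preset not in PRESETS:
            raise ValueError(f"unknown eligibility preset {self.preset!r}")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        raw = dict(raw)
        if raw.get("generator") is not None:
            gen = dict(raw["generator"])
            for key in ("race_mix", "rs_dist_per_race", "theta_per_race"):
                if key in gen and isinstance(gen[key], dict):
                    gen[key] = {k: tuple(v) if isinstance(v, list) else v
                                for k, v in gen[key].items()}
            if "age_range" in gen:
                gen["age_range"] = tuple(gen["age_range"])
            raw["generator"] = SyntheticConfig(**gen)
        if raw.get("rsf") is not None and not isinstance(raw["rsf"], RSFConfig):
            rsf = dict(raw["rsf"])
            if "features" in rsf:
                rsf["features"] = tuple(rsf["features"])
            raw["rsf"] = RSFConfig(**rsf)
        for key in ("covariates", "guideline_cutoffs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """All pipeline outputs plus provenance; serializable to JSON."""

    cohort_summary: pd.DataFrame | None = None
    cox_table: pd.DataFrame | None = None
    c_index_with_rs: float | None = None
    c_index_without_rs: float | None = None
    stratified_hr: pd.DataFrame | None = None
    rs_rank_tests: dict = field(default_factory=dict)
    threshold_overall: dict | None = None
    thresholds_by_race: dict = field(default_factory=dict)
    race_threshold_tests: dict = field(default_factory=dict)
    fold_changes: dict = field(default_factory=dict)
    ground_truth: dict | None = None
    provenance: dict = field(default_factory=dict)
    partial: bool = False
    failed_stage: str | None = None
    failure_message: str | None = None
    skipped: list = field(default_factory=list)

    def to_dict(self) -> dict:
        def frame(df):
            return None if df is None else df.to_dict(orient="records")
        return {
            "cohort_summary": frame(self.cohort_summary),
            "cox_table": frame(self.cox_table),
            "c_index_with_rs": self.c_index_with_rs,
            "c_index_without_rs": self.c_index_without_rs,
            "stratified_hr": frame(self.stratified_hr),
            "rs_rank_tests": {f"{a}_vs_{b}": p for (a, b), p in self.rs_rank_tests.items()},
            "threshold_overall": self.threshold_overall,
            "thresholds_by_race": self.thresholds_by_race,
            "race_threshold_tests": {f"{a}_vs_{b}": p for (a, b), p in self.race_threshold_tests.items()},
            "fold_changes": self.fold_changes,
            "ground_truth": self.ground_truth,
            "provenance": self.provenance,
            "partial": self.partial,
            "failed_stage": self.failed_stage,
            "failure_message": self.failure_message,
            "skipped": self.skipped,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True, default=float)


def run_full_analysis(config: AnalysisConfig, out_dir=None) -> AnalysisReport:
    """Run every stage in order; identical config + seed gives identical results."""
    report = AnalysisReport()
    report.provenance = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "version": __version__,
        "preset": config.preset,
    }
    stage = "load_cohort"
    try:
        logger.info("stage=%s seed=%s", stage, config.master_seed)
        if config.generator is not None:
            gen = dataclasses.replace(config.generator, seed=config.master_seed)
            cohort, truth = generate_cohort(gen)
            report.ground_truth = dataclasses.asdict(truth)
        else:
            cohort = read_cohort(config.input_path)

        stage = "eligibility"
        logger.info("stage=%s preset=%s", stage, config.preset)
        cohort = apply_eligibility(cohort, PRESETS[config.preset])
        if len(cohort) == 0:
            raise ValueError("no patients remain after eligibility filtering")
        cohort = cohort.reset_index(drop=True)

        stage = "cohort_summary"
        logger.info("stage=%s n=%d", stage, len(cohort))
        report.cohort_summary = summarize_cohort(cohort)

        stage = "cox"
        logger.info("stage=%s covariates=%s", stage, config.covariates)
        covs = [c for c in config.covariates
                if c in ("age", "rs", "risk_category") or cohort[c].nunique() > 1]
        fit_with = fit_cox(cohort, covs)
        report.cox_table = fit_with.table
        report.c_index_with_rs = concordance_index(fit_with, cohort)
        covs_without = [c for c in covs if c != "risk_category"]
        fit_without = fit_cox(cohort, covs_without)
        report.c_index_without_rs = concordance_index(fit_without, cohort)

        stage = "stratified_hr"
        logger.info("stage=%s", stage)
        tables = [chemo_hr_by_group(cohort)]
        for race in ("white", "black", "asian"):
            if (cohort["race"] == race).sum() >= config.min_race_n:
                tables.append(chemo_hr_by_group(cohort, race_subset=race))
        report.stratified_hr = pd.concat(tables, ignore_index=True)

        stage = "rs_rank_tests"
        races_present = [r for r in ("white", "black", "asian")
                         if (cohort["race"] == r).sum() > 0]
        for i, a in enumerate(races_present):
            for b in races_present[i + 1:]:
                res = rank_test(cohort.loc[cohort["race"] == a, "rs"],
                                cohort.loc[cohort["race"] == b, "rs"])
                report.rs_rank_tests[(a, b)] = res.pvalue

        stage = "threshold_overall"
        logger.info("stage=%s trees=%d iters=%d", stage, config.rsf.n_trees, config.n_iter)
        rsf_cfg = dataclasses.replace(config.rsf, seed=config.master_seed)
        point, curve = estimate_threshold(cohort, rsf_cfg,
                                          span=config.span, persistence=config.persistence)
        estimate = bootstrap_thresholds(
            cohort, rsf_cfg, n_iter=config.n_iter, fraction=config.subsample_fraction,
            master_seed=config.master_seed, span=config.span,
            persistence=config.persistence, point_estimate=point)
        report.threshold_overall = estimate.to_dict()
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            curve.to_frame().to_csv(Path(out_dir) / "rel_risk_curve_overall.csv", index=False)
            _plot_curve(curve, point, Path(out_dir) / "rel_risk_curve_overall.png")

        stage = "thresholds_by_race"
        race_ns = {r: int((cohort["race"] == r).sum()) for r in ("white", "black", "asian")}
        if config.by_race and all(n >= config.min_race_n for n in race_ns.values()):
            estimates, pairwise = race_specific_thresholds(
                cohort, rsf_cfg, min_n=config.min_race_n,
                n_iter=config.n_iter, fraction=config.subsample_fraction,
                master_seed=config.master_seed, span=config.span,
                persistence=config.persistence)
            report.thresholds_by_race = {
                r: (None if est is None else est.to_dict()) for r, est in estimates.items()}
            report.race_threshold_tests = {pair: res.pvalue for pair, res in pairwise.items()}
        else:
            small = [r for r, n in race_ns.items() if n < config.min_race_n]
            reason = (f"per-race analysis skipped: race subsets below minimum "
                      f"{config.min_race_n}: {small}" if config.by_race
                      else "per-race analysis disabled")
            logger.info("stage=%s skipped (%s)", stage, reason)
            report.skipped.append(reason)

        stage = "fold_changes"
        thresholds = {"overall": estimate.median}
        for race, est in report.thresholds_by_race.items():
            if est is not None and est["median"] is not None:
                thresholds[race] = est["median"]
        for label, thr in thresholds.items():
            if thr is None or np.isnan(thr):
                continue
            sub = cohort if label == "overall" else cohort[cohort["race"] == label]
            report.fold_changes[label] = {
                str(int(cut)): fold_change(sub, thr, cut).to_dict()
                for cut in config.guideline_cutoffs}
    except Exception as exc:  # noqa: BLE001 - stage failures make a partial report
        logger.exception("stage %s failed", stage)
        report.partial = True
        report.failed_stage = stage
        report.failure_message = str(exc)

    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        report.to_json(Path(out_dir) / "report.json")
    return report


def _plot_curve(curve, threshold, path) -> None:
    """Plain rendering of the smoothed relative-risk curve; styling is not a goal."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.rs_grid, curve.values, color="tab:blue")
    ax.axhline(0.0, color="black", lw=0.8)
    if threshold is not None:
        ax.axvline(threshold, color="black", ls="--", lw=0.8,
                   label=f"threshold RS {threshold:.1f}")
        ax.legend()
    ax.set_xlabel("recurrence score")
    ax.set_ylabel("relative risk (risk.yes - risk.no)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Worked small datasets used throughout the unit tests

def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write the small worked datasets plus one medium synthetic cohort.

    Returns a mapping of fixture name to path.  Deterministic in ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def cohort_frame(rows):
        base = {"stage": "I", "grade": "moderate", "er_status": "positive",
                "pr_status": "positive", "subtype": "luminalA",
                "ln_status": "negative", "race": "white", "age": 60.0,
                "rs": 20.0, "chemo": "no_unknown", "event": "bcss_death"}
        recs = []
        for i, row in enumerate(rows):
            rec = dict(base)
            rec["id"] = f"F{i:03d}"
            rec.update(row)
            recs.append(rec)
        from .cohort_model import COLUMNS
        return pd.DataFrame(recs)[COLUMNS]

    # 8-patient Cox set: times 1..8, all events, binary treatment covariate.
    cox8 = cohort_frame([
        {"time_months": t, "chemo": "yes" if t % 2 == 0 else "no_unknown"}
        for t in range(1, 9)])
    paths["cox8"] = out / "cox8.csv"
    write_cohort(cox8, paths["cox8"])

    # 3-patient Nelson-Aalen set: events at months 1, 2, 3.
    na3 = cohort_frame([{"time_months": t} for t in (1, 2, 3)])
    paths["na3"] = out / "na3.csv"
    write_cohort(na3, paths["na3"])

    # 7-row eligibility set: row 0 eligible, rows 1-6 each violate one criterion.
    elig = cohort_frame([
        {"time_months": 10},
        {"time_months": 10, "stage": "III"},
        {"time_months": 10, "er_status": "negative"},
        {"time_months": 10, "subtype": "luminalB"},
        {"time_months": 10, "age": 34.0},
        {"time_months": 10, "age": 81.0},
        {"time_months": 10, "rs": np.nan},
    ])
    paths["eligibility7"] = out / "eligibility7.csv"
    write_cohort(elig, paths["eligibility7"])

    # 5-value fold-change set: RS 10, 20, 26, 31, 35.
    fold5 = cohort_frame([{"time_months": 10, "rs": float(r)}
                          for r in (10, 20, 26, 31, 35)])
    paths["fold5"] = out / "fold5.csv"
    write_cohort(fold5, paths["fold5"])

    # Medium synthetic cohort with ground-truth sidecar.
    gen = SyntheticConfig(n_patients=5000, seed=seed)
    cohort, truth = generate_cohort(gen)
    paths["cohort_medium"] = out / "cohort_medium.csv"
    paths["cohort_medium_truth"] = out / "cohort_medium_truth.json"
    write_cohort(cohort, paths["cohort_medium"])
    truth.to_json(paths["cohort_medium_truth"])
    return paths
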