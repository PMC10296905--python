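"""Random survival forest with counterfactual treatment predictions.

The forest models breast-cancer-specific survival from the recurrence score,
race, age and chemotherapy status.  Because chemotherapy is one of the
predictors, the fitted ensemble supports a counterfactual query: predict a
patient's mortality twice, once with the treatment variable forced to yes
(``risk_yes``) and once forced to no (``risk_no``), all other covariates
untouched.  Their difference ``rel_risk = risk_yes - risk_no`` is negative
where the model predicts chemotherapy benefit; the benefit threshold is
where the smoothed ``rel_risk`` curve crosses zero (see
:mod:`.threshold_estimation`).

The ensemble is backed by :class:`sksurv.ensemble.RandomSurvivalForest`
(log-rank split rule, Nelson-Aalen cumulative-hazard estimates in terminal
nodes, per-tree bootstrap resampling, seeded determinism).  "Mortality" is
the survival-forest literature's scalar risk score: the sum of the
ensemble-averaged cumulative hazard over the training event-time grid.  A
fixed-horizon cumulative-incidence score is available behind
``risk_kind="cumulative_incidence"``.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sksurv.ensemble import RandomSurvivalForest
from sksurv.util import Surv

_CHEMO_CODE = {"no_unknown": 0.0, "yes": 1.0}


class UnfittableError(ValueError):
    """The cohort cannot support a survival forest (e.g. no events)."""


class FeatureSchemaError(KeyError):
    """A required feature is absent or mismatched; names the field."""


class TreatmentContractError(ValueError):
    """Counterfactual query on a model fitted without the treatment variable."""


@dataclass(frozen=True)
class RSFConfig:
    """Forest hyperparameters.

    ``mtry`` is the number of candidate feature columns per split (default
    ceil(sqrt(p)) over the encoded columns).  ``min_node_events`` bounds the
    terminal node size (mapped to the backing library's minimum samples per
    leaf).  ``resample_fraction`` is the per-tree bootstrap draw as a
    fraction of n, with replacement (None = full n, the classic forest
    convention); ``bootstrap=False`` grows every tree on the full sample.
    """

    n_trees: int = 1000
    features: tuple = ("rs", "race", "age", "chemo")
    mtry: int | None = None
    min_node_events: int = 15
    resample_fraction: float | None = None
    bootstrap: bool = True
    risk_kind: str = "mortality"          # or "cumulative_incidence"
    horizon: float = 120.0                # months; used by cumulative_incidence only
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be at least 1")
        if self.risk_kind not in ("mortality", "cumulative_incidence"):
            raise ValueError("risk_kind must be 'mortality' or 'cumulative_incidence'")


@dataclass
class RSFModel:
    """Fitted ensemble plus the feature-encoding schema it was trained with."""

    estimator: RandomSurvivalForest
    feature_columns: tuple
    config: RSFConfig
    event_time_grid: np.ndarray

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "RSFModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError(f"{path!r} does not contain an RSFModel")
        return model


def encode_features(cohort: pd.DataFrame, features: tuple,
                    columns: tuple | None = None) -> pd.DataFrame:
    """Numeric design matrix for the forest.

    rs and age pass through as ordered numerics; chemo is coded yes=1,
    no_unknown=0; race expands to one indicator column per level.  When
    ``columns`` is given (prediction time) the result is aligned to that
    training schema, raising on novel race levels.
    """
    pieces = []
    for feat in features:
        if feat not in cohort.columns:
            raise FeatureSchemaError(f"feature {feat!r} missing from cohort")
        col = cohort[feat]
        if feat == "chemo":
            bad = ~col.isin(_CHEMO_CODE)
            if bad.any():
                raise FeatureSchemaError("chemo contains values outside {yes, no_unknown}")
            pieces.append(col.map(_CHEMO_CODE).rename("chemo"))
        elif feat == "race":
            for lv in sorted(col.unique()):
                pieces.append((col == lv).astype(float).rename(f"race[{lv}]"))
        else:
            pieces.append(col.astype(float).rename(feat))
    X = pd.concat(pieces, axis=1)
    X.index = cohort.index
    if columns is not None:
        novel = [c for c in X.columns if c not in columns and c.startswith("race[")]
        if novel:
            raise FeatureSchemaError(f"race level(s) unseen at fit time: {novel}")
        X = X.reindex(columns=list(columns), fill_value=0.0)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise FeatureSchemaError(f"missing values in feature(s) {bad}")
    return X


def fit_rsf(cohort: pd.DataFrame, config: RSFConfig = RSFConfig()) -> RSFModel:
    """Grow the survival forest on a cohort.

    Each tree is grown on an independent bootstrap resample; splits maximise
    the log-rank statistic among ``mtry`` randomly chosen candidate columns;
    terminal nodes carry Nelson-Aalen cumulative-hazard estimates on their
    own data.  A fixed seed makes refits bit-identical.
    """
    events = (cohort["event"] == "bcss_death").to_numpy()
    if not events.any():
        raise UnfittableError("cohort has no events; survival forest is unfittable")
    X = encode_features(cohort, config.features)
    y = Surv.from_arrays(events, cohort["time_months"].to_numpy(dtype=float))
    mtry = config.mtry if config.mtry is not None else math.ceil(math.sqrt(X.shape[1]))
    est = RandomSurvivalForest(
        n_estimators=config.n_trees,
        max_features=min(mtry, X.shape[1]),
        min_samples_leaf=config.min_node_events,
        min_samples_split=max(2, 2 * config.min_node_events),
        bootstrap=config.bootstrap,
        max_samples=config.resample_fraction,
        n_jobs=1,
        random_state=config.seed,
    )
    est.fit(X.to_numpy(dtype=float), y)
    return RSFModel(
        estimator=est,
        feature_columns=tuple(X.columns),
        config=config,
        event_time_grid=np.asarray(est.unique_times_, dtype=float),
    )


def predict_mortality(model: RSFModel, cohort: pd.DataFrame) -> np.ndarray:
    """Per-patient scalar risk from the ensemble.

    For ``risk_kind="mortality"`` (default): the sum over the training
    event-time grid of the tree-averaged Nelson-Aalen cumulative hazard.
    For ``"cumulative_incidence"``: 1 - S(horizon) from the ensemble
    survival function.  Deterministic given (model, input).
    """
    X = encode_features(cohort, model.config.features, columns=model.feature_columns)
    if model.config.risk_kind == "mortality":
        return model.estimator.predict(X.to_numpy(dtype=float))
    surv = model.estimator.predict_survival_function(X.to_numpy(dtype=float), return_array=True)
    grid = model.event_time_grid
    idx = np.searchsorted(grid, model.config.horizon, side="right") - 1
    if idx < 0:
        return np.zeros(len(cohort))
    return 1.0 - surv[:, idx]


def counterfactual_risks(model: RSFModel, cohort: pd.DataFrame,
                         require_treatment: bool = True) -> pd.DataFrame:
    """risk_yes / risk_no / avg_risk / rel_risk for every patient.

    risk_yes (risk_no) is the mortality prediction with the chemotherapy
    variable forced to yes (no) and every other covariate untouched;
    avg_risk = (risk_yes + risk_no)/2 and rel_risk = risk_yes - risk_no by
    definition, so a patient's factual prediction equals whichever
    counterfactual matches their observed treatment.
    """
    if require_treatment and "chemo" not in model.config.features:
        raise TreatmentContractError(
            "model was fitted without the treatment variable; counterfactuals undefined")
    forced_yes = cohort.assign(chemo="yes")
    forced_no = cohort.assign(chemo="no_unknown")
    risk_yes = predict_mortality(model, forced_yes)
    risk_no = predict_mortality(model, forced_no)
    return pd.DataFrame({
        "id": cohort["id"].to_numpy(),
        "rs": cohort["rs"].to_numpy(dtype=float),
        "risk_yes": risk_yes,
        "risk_no": risk_no,
        "avg_risk": (risk_yes + risk_no) / 2.0,
        "rel_risk": risk_yes - risk_no,
    }, index=cohort.index)
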