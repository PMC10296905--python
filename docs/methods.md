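# Methods

`chemothresh` estimates the recurrence-score (RS) value at which adjuvant
chemotherapy begins to confer a predicted survival benefit in early-stage
ER+/HER2− breast cancer, and quantifies how that threshold varies by race.
This note documents the statistical model, the estimation procedure, the
synthetic-cohort generator used for validation, and the numerical and design
choices a user or reviewer would want to audit.

## The estimation problem

Guideline practice dichotomizes the Oncotype DX recurrence score at fixed
cutoffs (chemotherapy recommended above RS 25 or RS 30, depending on
context; the registry risk categories break at 18 and 30).  Whether those
cutoffs sit at the score where chemotherapy actually starts to help is an
empirical question, and it need not have the same answer in every racial
group.  A Cox proportional-hazards model cannot answer it directly: the
treatment effect there is a single log-hazard ratio, and confounding by
indication (sicker, higher-score patients are treated more often) biases
the naive chemotherapy coefficient toward harm.

The package's approach is counterfactual prediction from a flexible
outcome model:

1. Fit a random survival forest for breast-cancer-specific survival (BCSS)
   on `(rs, race, age, chemo)`.
2. For every patient, predict twice with the treatment variable forced to
   each arm: `risk_yes` and `risk_no`, all other covariates untouched.
   "Risk" is ensemble mortality — the sum over the training event-time grid
   of the forest-averaged Nelson–Aalen cumulative hazard — the standard
   scalar risk score of survival forests.  A bounded fixed-horizon
   alternative, 1 − S(120 months), is available via
   `RSFConfig(risk_kind="cumulative_incidence")`.
3. Smooth `rel_risk = risk_yes − risk_no` against RS with loess and locate
   the zero crossing: below the crossing the model predicts net harm from
   chemotherapy, above it net benefit.
4. Quantify uncertainty by a subsample bootstrap: redo (1)–(3) on random
   70% subsets and summarize the crossing locations by median and IQR.
5. Compare races by running (1)–(4) within each race and comparing the
   bootstrap threshold distributions with rank tests, and translate
   thresholds into patient counts via fold changes against the guideline
   cutoffs: `count(RS > threshold) / count(RS > cutoff)`.

## Survival forest

The ensemble is scikit-survival's `RandomSurvivalForest`: per-tree bootstrap
resampling, log-rank split selection among `mtry` random candidate columns,
Nelson–Aalen cumulative-hazard estimates in terminal nodes, predictions
averaged over trees.  Defaults: 1,000 trees for a full analysis (validation
runs use 200; threshold dispersion is dominated by data sampling rather
than by the size of the ensemble); `mtry = ceil(sqrt(p))`
over the encoded columns; minimum terminal-node size 15 (samples per leaf —
the convention of the survival-forest software family this follows);
full-size bootstrap with replacement per tree.  Race enters as one-hot
indicator columns; RS and age as ordered numerics; chemotherapy as a binary
indicator whose `no_unknown` level conflates untreated with unreported
treatment (a registry coding limitation, flagged in cohort summaries).

Predictions are full-ensemble (in-bag); fixed seeds make refits
bit-identical, and fitted models serialize losslessly.

Survival times are whole months with a floor of one month, as registries
report follow-up.  This also bounds the forest's event-time grid (≤ the
administrative horizon in months), which keeps the per-node hazard arrays
small; with continuous times every observation is its own grid point and
memory grows quadratically in effect.

## Smoothing and crossing detection

Loess here is local-linear regression with the tricube kernel: for each
point of a 0.1-RS grid, the nearest `ceil(span·n)` observations define the
bandwidth, and a weighted straight line is fitted and evaluated.  Default
span 0.75.  The grid is restricted to the central 99% of the cohort's
scores ([0.5th, 99.5th] percentiles): with the default span the local
window covers most of the sample even at the grid ends, so the fit stays
well supported there, while the extreme half-percent tails — where even a
wide window runs out of neighbours on one side — are excluded.  A true
threshold beyond the grid is unrecoverable by construction, and one in the
last reachable percentiles is found only in the bootstrap iterations whose
data resolve it (the black-race validation below sits in this regime).

A reported threshold is a *persistent sign change*: a grid point where the
smoothed curve switches sign class (≤ 0 versus > 0) with the preceding
`persistence` grid points all on the old side and the following
`persistence` points all on the new side (default 5 points = 0.5 RS units,
windows truncated at the grid ends).  The crossing location is linearly
interpolated between the bracketing grid points.  Two-sided persistence is
deliberate: a one-sided rule ("first point ≤ 0 that stays ≤ 0") cannot
reject brief touch-and-return dips at their recovery edge and misidentifies
curves that enter the searched range already negative.  `None` is a valid
result, meaning no persistent crossing inside the searched range.

## Subsample bootstrap

Each of `n_iter = 10` iterations draws 70% of rows *without* replacement
(the procedure selects a subset; a with-replacement mode exists behind a
flag), refits the forest with an iteration-specific seed, and re-locates
the crossing.  Iteration seeds derive from one master seed by a documented
counter scheme (`SeedSequence([master, i])`, reduced to 31 bits), so every
estimate is reproducible from `(cohort, config, master seed)`.  Median and
IQR use midpoint-interpolated quantiles over the iterations that found a
crossing; an estimate in which no iteration crossed carries an explicit
`no_threshold` flag.  Note the subsamples overlap pairwise by ~49% of rows,
so the IQR measures stability of the fit, not full sampling variance.

## Cox descriptives

Cox models (lifelines; Efron tie handling, Wald 95% intervals
`exp(coef ± 1.96·se)`) provide the conventional companion analyses:
multivariate hazard ratios against declared reference levels (low risk
category, white race, well-differentiated, stage I, chemotherapy
`no_unknown`), Harrell concordance with and without the risk
classification, and univariate chemotherapy hazard ratios stratified by
risk category, where a stratum with fewer than two events in either arm is
marked not estimable rather than fitted.  Between-group score comparisons
use the Mann–Whitney test (exact null when both n ≤ 12 and untied, normal
approximation with tie correction otherwise); these groups share no pairing
key, so the unpaired form is the appropriate rank test, with a paired
Wilcoxon mode available.

## Synthetic validation cohorts

Real linked registry data with recurrence scores is access-restricted, so
validation uses a generator whose ground truth is known:

| parameter | default | meaning |
|---|---|---|
| `race_mix` | white .843 / black .083 / asian .074 | registry-like composition |
| `rs_dist_per_race` | N(17, 8), black N(19, 8), truncated to [0,100], integer | black mean ~2 RS above others |
| `age_range` | U(35, 80) years | eligibility window |
| `baseline_hazard` | 0.002 /month | BCSS hazard at RS 0, age 60, untreated |
| `beta_rs` | 0.03 /RS unit | score is prognostic |
| `beta_age` | 0.2 /decade | age effect, centred at 60 |
| `theta_per_race` | 25 | true benefit threshold θ |
| `benefit_slope` | 0.02 /RS unit | treatment log-HR γ(RS) = −s·(RS − θ) |
| `propensity_a, _b` | −2, 0.08 | P(chemo) = logistic(a + b·RS) |
| `censor_time_max` | 120 months | administrative censoring |
| `dropout_rate` | 0.003 /month | independent exponential dropout (~30% by 10 years) |

Event times are exponential under the proportional-hazards rate
λ0·exp(β_rs·RS + β_age·(age−60)/10 + chemo·γ(RS)); the treatment effect
changes sign exactly at θ.  With the defaults roughly a quarter to a third
of patients die of disease within the 120-month horizon, and a similar
share receive chemotherapy, rising with RS — confounding by indication is
built in.  Columns are drawn
in a fixed order from one seeded stream, so generation is bit-reproducible.
`true_relative_risk` gives the closed-form counterfactual risk difference
for any configuration, the oracle for recovery tests.

What the generator does *not* emulate: correlation between RS and age or
grade, non-proportional hazards, competing mortality, informative censoring,
calendar-time trends, and registry miscoding beyond the `no_unknown`
chemotherapy level.  Passing recovery tests therefore demonstrates that the
pipeline recovers thresholds *under its own assumed data-generating
structure*, not that the modelling assumptions hold in any real registry.

## Validation scale and results of record

The acceptance checks (mirrored in `tests/test_acceptance.py` and
`scripts/acceptance.py`) run at n = 20,000 patients with 200 trees — sizes
at which a bootstrap threshold run completes in minutes on one CPU while
leaving the data-level noise regime representative.  The primary check
requires the bootstrap median to land within 3 RS units of θ = 25; the
race-stratified check (θ = 20/37/18 for white/black/asian at
n = 15,000/5,000/5,000) requires the recovered medians to reproduce the
true ordering with the black thresholds significantly above both others.
θ = 37 sits near the 99th percentile of the black score distribution, so
only the bootstrap iterations whose subsample resolves the far tail locate
a crossing there (the rest correctly report none); the recovered black
median slightly under-shoots, and the ordering — what the race comparison
asserts — is robust.

## Known limitations

- **A threshold is always a point on a noisy curve.**  The smoothed
  relative-risk curve carries sampling noise from the data itself that
  growing a larger forest cannot remove.
  Under a true null treatment effect the curve wanders around zero and a
  persistent crossing generally still exists, so the estimator *reports a
  threshold even when there is no benefit boundary to find*.  A reported
  threshold should never be read as evidence of effect modification on its
  own; consult the bootstrap dispersion, the stratified chemotherapy hazard
  ratios, and the depth of the negative excursion before interpreting it.
- In-bag prediction overfits each patient's own outcome; out-of-bag
  prediction was not used because the counterfactual query (predicting a
  patient under both arms) has no out-of-bag analogue for the flipped arm.
- The `no_unknown` treatment level dilutes the treated/untreated contrast
  toward the null wherever treatment is underreported.
- Thresholds outside the central 99% of a group's score distribution are
  not recoverable by construction (see above).
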