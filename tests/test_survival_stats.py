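"""Cox fitting against brute-force oracles, concordance, stratified HRs, rank tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chemothresh import (CoxFitError, SyntheticConfig, chemo_hr_by_group,
                         concordance_index, fit_cox, generate_cohort,
                         harrell_c, rank_test)
from conftest import build_cohort


# ---------------------------------------------------------------------------
# oracles

def cox_partial_loglik(beta, times, events, x):
    """Explicit Cox partial log-likelihood (no ties; Breslow = Efron here)."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    total = 0.0
    for i in range(len(times)):
        if events[i]:
            risk_set = x[times >= times[i]]
            total += beta * x[i] - np.log(np.sum(np.exp(beta * risk_set)))
    return total


def brute_force_concordance(times, events, risks):
    """O(n^2) pair enumeration of Harrell's C."""
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i]:
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
    return num / den


# ---------------------------------------------------------------------------

def test_eight_patient_fit_matches_partial_likelihood_grid(cox8_cohort):
    """The returned coefficient is the arg-max of the explicitly enumerated
    partial likelihood on a 1e-4 grid."""
    fit = fit_cox(cox8_cohort, ["chemo"])
    beta_hat = fit.table.loc[0, "coef"]
    times = cox8_cohort["time_months"].to_numpy()
    events = np.ones(len(times), dtype=bool)
    x = (cox8_cohort["chemo"] == "yes").to_numpy(dtype=float)
    grid = np.arange(-3.0, 3.0, 1e-4)
    values = [cox_partial_loglik(b, times, events, x) for b in grid]
    beta_grid = grid[int(np.argmax(values))]
    assert beta_hat == pytest.approx(beta_grid, abs=1e-3)


def test_partial_likelihood_is_maximized_at_fit(cox8_cohort):
    fit = fit_cox(cox8_cohort, ["chemo"])
    beta_hat = fit.table.loc[0, "coef"]
    times = cox8_cohort["time_months"].to_numpy()
    events = np.ones(len(times), dtype=bool)
    x = (cox8_cohort["chemo"] == "yes").to_numpy(dtype=float)
    best = cox_partial_loglik(beta_hat, times, events, x)
    for b in np.linspace(beta_hat - 1.0, beta_hat + 1.0, 41):
        assert cox_partial_loglik(b, times, events, x) <= best + 1e-9


def _two_arm_cohort(rng, n=400, log_hr=0.7):
    treated = rng.random(n) < 0.5
    lam = 0.05 * np.exp(log_hr * treated)
    times = rng.exponential(1.0 / lam)
    return build_cohort([
        {"time_months": float(t), "chemo": "yes" if z else "no_unknown"}
        for t, z in zip(times, treated)])


def test_two_group_exponential_recovery():
    rng = np.random.default_rng(100)
    fit = fit_cox(_two_arm_cohort(rng), ["chemo"])
    row = fit.table.iloc[0]
    assert abs(row["coef"] - 0.7) < 3 * row["se"]


def test_permuted_labels_are_null():
    """Randomly permuting the treatment label kills the effect: |coef| < 2 se
    in at least 95 of 100 replicates."""
    rng = np.random.default_rng(200)
    base = _two_arm_cohort(rng)
    hits = 0
    for _ in range(100):
        shuffled = base.assign(chemo=rng.permutation(base["chemo"].to_numpy()))
        row = fit_cox(shuffled, ["chemo"]).table.iloc[0]
        hits += abs(row["coef"]) < 2 * row["se"]
    assert hits >= 95


def test_hr_columns_reproduce_exp_of_coefficients():
    rng = np.random.default_rng(300)
    cohort = _two_arm_cohort(rng, n=200)
    cohort["age"] = rng.uniform(35, 80, len(cohort))
    fit = fit_cox(cohort, ["chemo", "age"])
    t = fit.table
    assert np.allclose(t["HR"], np.exp(t["coef"]))
    assert np.allclose(t["ci_low"], np.exp(t["coef"] - 1.96 * t["se"]))
    assert np.allclose(t["ci_high"], np.exp(t["coef"] + 1.96 * t["se"]))
    assert ((t["ci_low"] <= t["HR"]) & (t["HR"] <= t["ci_high"])).all()


def test_too_few_events_rejected():
    cohort = build_cohort([{"time_months": 5.0, "event": "censored"}] * 10)
    with pytest.raises(CoxFitError):
        fit_cox(cohort, ["age"])


class TestConcordance:
    def test_perfect_ranking_gives_one(self):
        cohort = build_cohort([{"time_months": float(t), "age": 80.0 - t}
                               for t in range(1, 21)])
        fit = fit_cox(cohort, ["age"])
        assert concordance_index(fit, cohort) == pytest.approx(1.0)

    def test_constant_predictions_give_half(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, 30)
        assert harrell_c(times, np.ones(30, int), np.zeros(30)) == pytest.approx(0.5)

    def test_matches_brute_force_on_random_censored_instances(self):
        """Harrell's C equals O(n^2) pair enumeration exactly, including
        prediction ties, on random instances with ~30% censoring."""
        rng = np.random.default_rng(1234)
        for _ in range(25):
            n = int(rng.integers(10, 101))
            times = rng.exponential(10, n)  # a.s. distinct
            events = (rng.random(n) > 0.3).astype(int)
            if events.sum() == 0:
                events[0] = 1
            risks = rng.choice([0.0, 0.5, 1.0, 2.0], size=n)  # forces ties
            assert harrell_c(times, events, risks) == pytest.approx(
                brute_force_concordance(times, events, risks), abs=1e-12)

    def test_adding_risk_category_does_not_hurt_concordance(self):
        """On cohorts where the score is prognostic by construction, a Cox
        model with the risk classification has concordance at least that of
        the model without it."""
        cohort, _ = generate_cohort(SyntheticConfig(n_patients=4000, seed=31))
        with_rs = fit_cox(cohort, ["age", "risk_category", "chemo"])
        without_rs = fit_cox(cohort, ["age", "chemo"])
        c_with = concordance_index(with_rs, cohort)
        c_without = concordance_index(without_rs, cohort)
        assert c_with >= c_without


class TestStratifiedHR:
    def test_benefit_orders_stratum_hrs(self):
        """With a benefit threshold at RS 25, treated high-score patients do
        better than treated low-score patients: HR(high) < HR(low)."""
        cohort, _ = generate_cohort(SyntheticConfig(
            n_patients=20000, benefit_slope=0.02, seed=41))
        table = chemo_hr_by_group(cohort).set_index("stratum")
        assert table.loc["high", "estimable"] and table.loc["low", "estimable"]
        assert table.loc["high", "HR"] < table.loc["low", "HR"]

    def test_null_effect_cis_usually_contain_one(self):
        """With s=0 and no confounding the stratum CIs contain 1 in >= 90%
        of replicates."""
        contained = total = 0
        for seed in range(20):
            cohort, _ = generate_cohort(SyntheticConfig(
                n_patients=3000, benefit_slope=0.0, propensity_b=0.0,
                propensity_a=-1.0, seed=1000 + seed))
            table = chemo_hr_by_group(cohort)
            est = table[table["estimable"]]
            contained += ((est["ci_low"] <= 1) & (1 <= est["ci_high"])).sum()
            total += len(est)
        assert contained / total >= 0.90

    def test_stratum_without_chemo_marked_not_estimable(self):
        cohort = build_cohort([{"time_months": float(t), "rs": 10.0}
                               for t in range(1, 11)])
        table = chemo_hr_by_group(cohort).set_index("stratum")
        assert not table.loc["low", "estimable"]
        assert np.isnan(table.loc["low", "HR"])


class TestRankTest:
    def test_identical_samples_give_p_one(self):
        res = rank_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.pvalue == 1.0

    def test_fully_separated_samples_match_exact_enumeration(self):
        """a = 1..10 below b = 11..20: U = 0 and the exact two-sided p equals
        2 / C(20, 10), the share of rank assignments at least this extreme."""
        res = rank_test(list(range(1, 11)), list(range(11, 21)))
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(2.0 / math.comb(20, 10), rel=1e-12)

    def test_two_sided_p_symmetric_under_swap(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        assert rank_test(a, b).pvalue == pytest.approx(rank_test(b, a).pvalue)

    def test_paired_mode_runs(self):
        a = np.arange(1.0, 13.0)
        res = rank_test(a, a + np.tile([1.0, -0.5], 6), paired=True)
        assert 0 <= res.pvalue <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_test([], [1.0])
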