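"""Logistic fits, univariate screening, LASSO path and backward elimination."""

import numpy as np
import pytest
from scipy.special import expit

from thyroht.selection import (
    LassoConfig,
    backward_eliminate,
    fit_logistic,
    lasso_select,
    univariate_screen,
)

from conftest import make_dataset


def _sim_dataset(rng, n=1000, betas=(1.0, 0.0), beta0=0.0):
    """Two standard-normal predictors with a logistic outcome."""
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    y = rng.random(n) < expit(beta0 + betas[0] * x1 + betas[1] * x2)
    return make_dataset(strong=x1, noise=x2, ht_within_2y=y)


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        # 3:1 odds at x=1 vs 1:3 at x=0 -> OR = 9, coefficient log 9
        ds = make_dataset(
            x=[0, 0, 0, 0, 1, 1, 1, 1],
            ht_within_2y=[False, False, False, True, False, True, True, True],
        )
        fit = fit_logistic(ds, ["x"], increments={"x": 1.0}, min_events=1)
        assert fit.coef["x"] == pytest.approx(np.log(9.0), abs=1e-5)
        assert fit.odds_ratio["x"] == pytest.approx(9.0, abs=1e-4)

    def test_constant_predictor_rejected(self):
        ds = make_dataset(x=[1.0] * 30, ht_within_2y=[True, False] * 15)
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(ds, ["x"], min_events=1)

    def test_separation_detected(self):
        x = np.concatenate([np.zeros(15), np.ones(15)])
        ds = make_dataset(x=x, ht_within_2y=x > 0.5)
        from thyroht.selection import SeparationError

        with pytest.raises(SeparationError, match="x"):
            fit_logistic(ds, ["x"], min_events=1)

    def test_too_few_events_rejected(self):
        ds = make_dataset(x=np.arange(30.0), ht_within_2y=[True] * 3 + [False] * 27)
        with pytest.raises(ValueError, match="events"):
            fit_logistic(ds, ["x"])

    def test_scaling_equivariance(self, rng):
        ds = _sim_dataset(rng, n=600)
        base = fit_logistic(ds, ["strong"], increments={"strong": 1.0})
        scaled = make_dataset(
            strong=ds.frame["strong"] * 10.0, ht_within_2y=ds.frame["ht_within_2y"]
        )
        tenx = fit_logistic(scaled, ["strong"], increments={"strong": 10.0})
        assert tenx.coef["strong"] == pytest.approx(base.coef["strong"] / 10.0, rel=1e-6)
        assert tenx.odds_ratio["strong"] == pytest.approx(base.odds_ratio["strong"], rel=1e-6)
        assert tenx.p_values["strong"] == pytest.approx(base.p_values["strong"], rel=1e-6)
        assert tenx.log_likelihood == pytest.approx(base.log_likelihood, abs=1e-8)

    def test_wald_interval_ordering(self, rng):
        fit = fit_logistic(_sim_dataset(rng), ["strong", "noise"])
        for p in fit.predictors:
            assert fit.ci_low[p] <= fit.odds_ratio[p] <= fit.ci_high[p]

    def test_null_coverage(self, rng):
        """Under no effect, the 95% Wald CI covers OR = 1 about 95% of the time."""
        covered = 0
        for _ in range(60):
            ds = _sim_dataset(rng, n=400, betas=(0.0, 0.0))
            fit = fit_logistic(ds, ["strong"])
            covered += fit.ci_low["strong"] <= 1.0 <= fit.ci_high["strong"]
        assert covered >= 50  # binomial(60, .95) lower tail


class TestUnivariateScreen:
    def test_strong_effect_flagged_noise_mostly_not(self, rng):
        flagged_strong = flagged_noise = 0
        reps = 40
        for _ in range(reps):
            ds = _sim_dataset(rng, n=800)
            step, _ = univariate_screen(ds, ["strong", "noise"])
            flagged_strong += "strong" in step.selected
            flagged_noise += "noise" in step.selected
        assert flagged_strong == reps  # log-OR 1 at n=800 is near-certain power
        assert flagged_noise <= reps * 0.25  # ~5% type-I rate, generous bound

    def test_empty_predictor_list(self, rng):
        step, fits = univariate_screen(_sim_dataset(rng, n=100), [])
        assert step.selected == ()
        assert fits == {}

    def test_per_predictor_failures_recorded_not_fatal(self, rng):
        ds = _sim_dataset(rng, n=200)
        ds.frame["flat"] = 1.0
        step, fits = univariate_screen(ds, ["strong", "flat"])
        assert "flat" in step.detail["errors"]
        assert "strong" in fits


class TestLasso:
    def test_zero_penalty_selects_all(self, rng):
        ds = _sim_dataset(rng, n=300)
        selected, _ = lasso_select(ds, ["strong", "noise"], LassoConfig(penalty=0.0))
        assert set(selected) == {"strong", "noise"}

    def test_infinite_penalty_selects_none(self, rng):
        ds = _sim_dataset(rng, n=300)
        for lam in (1e6, np.inf):
            selected, _ = lasso_select(ds, ["strong", "noise"], LassoConfig(penalty=lam))
            assert selected == ()

    def test_cv_selects_true_predictor(self, rng):
        """Signal is never lost under either penalty rule; the sparser 1-SE
        rule also drops the pure-noise predictor in >= 90% of replicates
        (the min-deviance rule is deliberately anti-sparse and is not held
        to that)."""
        hits_min = hits_1se = drops_1se = 0
        reps = 20
        for _ in range(reps):
            ds = _sim_dataset(rng, n=1000, betas=(1.5, 0.0))
            sel_min, _ = lasso_select(ds, ["strong", "noise"], LassoConfig(fold_seed=7))
            sel_1se, _ = lasso_select(
                ds, ["strong", "noise"], LassoConfig(fold_seed=7, rule="1se")
            )
            hits_min += "strong" in sel_min
            hits_1se += "strong" in sel_1se
            drops_1se += "noise" not in sel_1se
        assert hits_min == reps
        assert hits_1se == reps
        assert drops_1se >= 0.9 * reps

    def test_one_se_rule_is_sparser_or_equal(self, rng):
        ds = _sim_dataset(rng, n=800, betas=(1.0, 0.0))
        sel_min, step_min = lasso_select(ds, ["strong", "noise"], LassoConfig(fold_seed=3))
        sel_1se, step_1se = lasso_select(
            ds, ["strong", "noise"], LassoConfig(fold_seed=3, rule="1se")
        )
        assert step_1se.detail["penalty"] >= step_min.detail["penalty"]
        assert set(sel_1se) <= set(sel_min)

    def test_fixed_fold_seed_reproducible(self, rng):
        ds = _sim_dataset(rng, n=500)
        a = lasso_select(ds, ["strong", "noise"], LassoConfig(fold_seed=11))
        b = lasso_select(ds, ["strong", "noise"], LassoConfig(fold_seed=11))
        assert a[0] == b[0]
        assert a[1].detail["penalty"] == b[1].detail["penalty"]


class TestBackwardElimination:
    def test_single_significant_predictor_fixed_point(self, rng):
        ds = _sim_dataset(rng, n=800)
        fit, trace = backward_eliminate(ds, ["strong"])
        assert fit.predictors == ("strong",)
        assert len(trace.steps) == 1

    def test_noise_dropped_strong_retained(self, rng):
        ds = _sim_dataset(rng, n=1200, betas=(1.2, 0.0))
        fit, trace = backward_eliminate(ds, ["strong", "noise"])
        assert "strong" in fit.predictors

    def test_trace_strictly_nested_and_terminates(self, rng):
        preds = ["strong", "noise"]
        ds = _sim_dataset(rng, n=400, betas=(0.0, 0.0))
        ds.frame["noise2"] = rng.normal(size=400)
        fit, trace = backward_eliminate(ds, preds + ["noise2"])
        sets = [set(s.selected) for s in trace.steps]
        for a, b in zip(sets, sets[1:]):
            assert b <= a
        assert len(trace.steps) <= 4
        survivors = set(fit.predictors) if fit else set()
        assert len(survivors) <= 1  # pure noise rarely survives; never all three

    def test_all_noise_usually_empty(self, rng):
        empties = 0
        reps = 20
        for _ in range(reps):
            ds = _sim_dataset(rng, n=600, betas=(0.0, 0.0))
            fit, _ = backward_eliminate(ds, ["strong", "noise"])
            empties += fit is None
        assert empties >= reps * 0.75  # ~(1-alpha)^2 of runs end empty
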