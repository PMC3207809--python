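"""Survival primitives: partial likelihood, Newton Cox fit, Kaplan-Meier,
log-rank, Breslow baseline."""

import numpy as np
import pandas as pd
import pytest

from omicox import (
    SurvivalOutcome,
    breslow_baseline,
    fit_cox_unpenalized,
    kaplan_meier,
    logrank_test,
    neg_log_partial_likelihood,
)
from omicox.survival import ConvergenceError, DegenerateDataError

from conftest import make_cox_instance


class TestPartialLikelihood:
    def test_value_at_zero_is_sum_of_log_risk_set_sizes(self, small_instance):
        X, y, _ = small_instance
        v, _ = neg_log_partial_likelihood(np.zeros(X.shape[1]), X, y)
        expected = sum(
            np.log((y.time >= ti).sum()) for ti, ei in zip(y.time, y.event) if ei
        )
        assert v == pytest.approx(expected, rel=1e-12)

    def test_three_sample_hand_enumeration(self):
        # times 1,2,3 all events, x=(1,0,0), beta=1:
        # risk sets {1,2,3}, {2,3}, {3} ->
        # nll = -(1 - log(e+2)) - (0 - log 2) - 0
        y = SurvivalOutcome([1.0, 2.0, 3.0], [1, 1, 1])
        X = np.array([[1.0], [0.0], [0.0]])
        v, _ = neg_log_partial_likelihood(np.array([1.0]), X, y)
        expected = -1.0 + np.log(np.e + 2.0) + np.log(2.0)
        assert v == pytest.approx(expected, rel=1e-12)

    def test_gradient_matches_central_finite_differences(self, small_instance):
        X, y, _ = small_instance
        rng = np.random.default_rng(3)
        beta = 0.3 * rng.standard_normal(X.shape[1])
        _, g = neg_log_partial_likelihood(beta, X, y)
        eps = 1e-6
        for k in range(X.shape[1]):
            e = np.zeros_like(beta)
            e[k] = eps
            fd = (
                neg_log_partial_likelihood(beta + e, X, y)[0]
                - neg_log_partial_likelihood(beta - e, X, y)[0]
            ) / (2 * eps)
            assert g[k] == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_all_censored_is_degenerate(self):
        y = SurvivalOutcome([1.0, 2.0], [0, 0])
        with pytest.raises(DegenerateDataError):
            neg_log_partial_likelihood(np.zeros(1), np.ones((2, 1)), y)


class TestUnpenalizedFit:
    def test_symmetric_groups_give_zero_coefficient(self):
        # identical event patterns in both groups -> no association
        times = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        x = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])[:, None]
        # jitter to break exact ties symmetrically? keep ties: Breslow handles them
        fit = fit_cox_unpenalized(x, SurvivalOutcome(times, events))
        assert abs(fit.beta[0]) < 1e-8

    def test_recovers_true_effect_at_n_1000(self):
        X, y, beta = make_cox_instance(1000, 1, beta=[0.7], seed=7)
        fit = fit_cox_unpenalized(X, y)
        assert fit.beta[0] == pytest.approx(0.7, abs=0.1)

    def test_agrees_with_lifelines_on_50x3(self, small_instance):
        from lifelines import CoxPHFitter

        X, y, _ = small_instance
        fit = fit_cox_unpenalized(X, y)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["T"], df["E"] = y.time, y.event
        cph = CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(fit.beta, cph.params_.to_numpy(), atol=1e-4)
        assert np.allclose(fit.standard_errors, cph.standard_errors_.to_numpy(), atol=1e-4)

    def test_separation_is_reported(self):
        # perfect separation: covariate orders times exactly, no censoring
        t = np.arange(1.0, 9.0)
        x = -t[:, None]
        with pytest.raises((ConvergenceError, ValueError)):
            fit_cox_unpenalized(x, SurvivalOutcome(t, np.ones(8, int)))

    def test_constant_column_rejected(self, small_instance):
        X, y, _ = small_instance
        X = X.copy()
        X[:, 0] = 2.5
        with pytest.raises(ValueError):
            fit_cox_unpenalized(X, y)


class TestKaplanMeier:
    def test_no_events_constant_one(self):
        km = kaplan_meier(SurvivalOutcome([1.0, 2.0, 3.0], [0, 0, 0]))
        assert km.knots.size == 0
        assert km(np.array([0.5, 10.0])) == pytest.approx([1.0, 1.0])

    def test_hand_product_limit(self):
        km = kaplan_meier(SurvivalOutcome([1.0, 2.0, 3.0], [1, 1, 1]))
        assert np.allclose(km.knots, [1, 2, 3])
        assert np.allclose(km.values, [2 / 3, 1 / 3, 0.0])

    def test_censoring_after_last_event_leaves_curve_unchanged(self):
        base = kaplan_meier(SurvivalOutcome([1.0, 2.0, 3.0], [1, 1, 1]))
        extended = kaplan_meier(SurvivalOutcome([1.0, 2.0, 3.0, 9.0], [1, 1, 1, 0]))
        # same drop times; survival values differ only via risk-set sizes
        assert np.allclose(extended.knots, base.knots)
        assert np.all(np.diff(extended.values) < 0)

    def test_matches_lifelines(self, small_instance):
        from lifelines import KaplanMeierFitter

        _, y, _ = small_instance
        km = kaplan_meier(y)
        kmf = KaplanMeierFitter().fit(y.time, y.event)
        ts = np.linspace(0.1, y.time.max(), 37)
        ours = km(ts)
        theirs = kmf.survival_function_at_times(ts).to_numpy()
        assert np.allclose(ours, theirs, atol=1e-10)


class TestLogrank:
    def test_identical_groups_give_null(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        e = np.array([1, 0, 1, 1, 1, 0, 1, 1])
        g = np.repeat(["a", "b"], 4)
        res = logrank_test(SurvivalOutcome(t, e), g)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_two_group_hand_accumulation(self):
        # independent observed-minus-expected accumulation over event times
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 1, 1, 0, 1])
        g = np.array([0, 1, 0, 1, 0, 1])
        y = SurvivalOutcome(t, e)
        O = E = V = 0.0
        for ti in np.unique(t[e == 1]):
            at_risk = t >= ti
            n_tot = at_risk.sum()
            n_1 = (at_risk & (g == 1)).sum()
            d_tot = ((t == ti) & (e == 1)).sum()
            d_1 = ((t == ti) & (e == 1) & (g == 1)).sum()
            O += d_1
            E += d_tot * n_1 / n_tot
            if n_tot > 1:
                V += (
                    d_tot * (n_1 / n_tot) * (1 - n_1 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
                )
        expected_chi2 = (O - E) ** 2 / V
        res = logrank_test(y, g)
        assert res.chi2 == pytest.approx(expected_chi2, rel=1e-10)
        assert res.df == 1

    def test_three_groups_have_two_df(self):
        t = np.arange(1.0, 10.0)
        e = np.ones(9, int)
        g = np.repeat(["a", "b", "c"], 3)
        assert logrank_test(SurvivalOutcome(t, e), g).df == 2

    def test_relabeling_invariance(self):
        X, y, _ = make_cox_instance(40, 1, beta=[0.8], seed=5)
        g = (X[:, 0] > 0).astype(int)
        r1 = logrank_test(y, g)
        r2 = logrank_test(y, 1 - g)
        assert r1.chi2 == pytest.approx(r2.chi2, rel=1e-12)

    def test_single_group_rejected(self):
        y = SurvivalOutcome([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            logrank_test(y, ["a", "a"])


class TestBreslowBaseline:
    def test_zero_beta_reduces_to_nelson_aalen(self, small_instance):
        X, y, _ = small_instance
        bb = breslow_baseline(np.zeros(X.shape[1]), X, y)
        order = np.argsort(y.time)
        increments = []
        for ti, ei in zip(y.time[order], y.event[order]):
            if ei:
                increments.append(1.0 / (y.time >= ti).sum())
        assert np.allclose(bb.values, np.cumsum(increments), rtol=1e-12)

    def test_nondecreasing(self, small_instance):
        X, y, _ = small_instance
        bb = breslow_baseline(np.array([0.4, -0.2, 0.1]), X, y)
        assert np.all(np.diff(bb.values) >= 0)

    def test_tracks_true_exponential_baseline(self):
        X, y, beta = make_cox_instance(3000, 1, beta=[0.6], seed=9, scale=40.0,
                                       censor_horizon=200.0)
        bb = breslow_baseline(beta, X, y)
        ts = np.linspace(2, 60, 30)
        S0 = np.exp(-bb(ts))
        truth = np.exp(-ts / 40.0)
        assert np.max(np.abs(S0 - truth)) < 0.05

    def test_consistent_with_km_at_zero_beta(self, small_instance):
        X, y, _ = small_instance
        bb = breslow_baseline(np.zeros(X.shape[1]), X, y)
        km = kaplan_meier(y)
        ts = np.linspace(0.5, y.time.max(), 25)
        # exp(-H0) approximates KM within O(1/|R|) increments on tie-free data
        assert np.max(np.abs(np.exp(-bb(ts)) - km(ts))) < 0.08
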