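"""Signature scores, tertile stratification, median time prediction and
the evaluation report."""

import numpy as np
import pandas as pd
import pytest

from omicox import (
    Signature,
    StepFunction,
    SurvivalOutcome,
    breslow_baseline,
    compute_scores,
    evaluate,
    predict_median_time,
    stratify,
)

from conftest import make_cox_instance


def _simple_signature(betas, means=None, scales=None, names=None):
    k = len(betas)
    return Signature(
        features=tuple(names or [f"f{i}" for i in range(k)]),
        betas=np.asarray(betas, float),
        means=np.asarray(means if means is not None else np.zeros(k), float),
        scales=np.asarray(scales if scales is not None else np.ones(k), float),
    )


class TestScores:
    def test_c_score_arithmetic(self):
        sig = _simple_signature([2.0])
        scores = compute_scores(sig, np.array([[1.5]]))
        assert scores.c_score[0] == pytest.approx(3.0)

    def test_t_score_difference_of_means(self):
        sig = _simple_signature([0.4, -0.3])  # one poor, one good feature
        scores = compute_scores(sig, np.array([[1.0, 0.4]]))
        assert scores.t_score[0] == pytest.approx(1.0 - 0.4)

    def test_c_score_linearity_under_shift(self):
        sig = _simple_signature([2.0, 1.0])
        X = np.random.default_rng(0).standard_normal((5, 2))
        base = compute_scores(sig, X).c_score
        shifted = X.copy()
        shifted[:, 0] += 1.0
        assert np.allclose(compute_scores(sig, shifted).c_score, base + 2.0)

    def test_missing_features_reported(self):
        sig = _simple_signature([1.0], names=["present"])
        X = pd.DataFrame({"other": [1.0, 2.0]})
        with pytest.raises(KeyError, match="present"):
            compute_scores(sig, X)

    def test_standardization_uses_stored_transform(self):
        sig = _simple_signature([1.0], means=[10.0], scales=[2.0])
        scores = compute_scores(sig, np.array([[14.0]]))
        assert scores.c_score[0] == pytest.approx(2.0)


class TestStratify:
    def test_interpolated_tertiles_on_one_to_nine(self):
        strata = stratify(np.arange(1.0, 10.0))
        assert strata.cutoffs[0] == pytest.approx(11 / 3)
        assert strata.cutoffs[1] == pytest.approx(19 / 3)
        sizes = pd.Series(strata.labels).value_counts()
        assert sizes["low"] == sizes["intermediate"] == sizes["high"] == 3

    def test_tie_goes_to_lower_stratum(self):
        strata = stratify(np.arange(1.0, 10.0), np.array([11 / 3]))
        assert strata.labels[0] == "low"

    def test_monotone_transform_preserves_assignment(self):
        rng = np.random.default_rng(1)
        train = rng.standard_normal(30)
        test = rng.standard_normal(10)
        a = stratify(train, test).labels
        b = stratify(np.exp(train), np.exp(test)).labels
        assert np.array_equal(a, b)

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError):
            stratify(np.ones(10))


class TestMedianTime:
    def test_closed_form_exponential_median(self):
        X, y, beta = make_cox_instance(2000, 1, beta=[0.6], seed=41, scale=40.0,
                                       censor_horizon=250.0)
        baseline = breslow_baseline(beta, X, y)
        med = predict_median_time(baseline, 0.0)
        assert med[0] == pytest.approx(40 * np.log(2), rel=0.1)

    def test_very_high_risk_predicts_at_most_first_event(self):
        X, y, beta = make_cox_instance(200, 1, beta=[0.5], seed=42)
        baseline = breslow_baseline(beta, X, y)
        med = predict_median_time(baseline, 50.0)
        assert med[0] <= y.time[y.event == 1].min() + 1e-9

    def test_low_risk_not_reached(self):
        baseline = StepFunction(np.array([5.0, 10.0]), np.array([0.01, 0.02]),
                                initial=0.0)
        med = predict_median_time(baseline, 0.0)
        assert np.isnan(med[0])

    def test_median_order_reverses_c_score_order(self):
        X, y, beta = make_cox_instance(500, 1, beta=[0.8], seed=43)
        baseline = breslow_baseline(beta, X, y)
        etas = np.linspace(-2, 2, 9)
        med = predict_median_time(baseline, etas)
        finite = ~np.isnan(med)
        assert np.all(np.diff(med[finite]) <= 0)


class TestEvaluate:
    def _fitted(self, seed=50, n=300):
        beta = np.r_[0.8, -0.8, np.zeros(8)]
        X, y, _ = make_cox_instance(n, 10, beta=beta, seed=seed)
        Xdf = pd.DataFrame(X, columns=[f"f{i}" for i in range(10)])
        mean, std = X[:200].mean(0), X[:200].std(0)
        sig = Signature(features=tuple(["f0", "f1"]), betas=np.array([0.8, -0.8]),
                        means=mean[:2], scales=std[:2])
        return sig, Xdf, y

    def test_self_evaluation_has_hr_above_one(self):
        sig, Xdf, y = self._fitted()
        report = evaluate(sig, Xdf, y, Xdf, y)
        hr = report.per_score["c_score"]["hr_high_vs_low"]
        assert hr is not None and hr > 1.0

    def test_report_is_deterministic(self):
        sig, Xdf, y = self._fitted()
        tr, te = Xdf.iloc[:200], Xdf.iloc[200:]
        ytr, yte = y.subset(range(200)), y.subset(range(200, 300))
        r1 = evaluate(sig, tr, ytr, te, yte)
        r2 = evaluate(sig, tr, ytr, te, yte)
        assert r1.per_score == r2.per_score
        pd.testing.assert_frame_equal(r1.median_times, r2.median_times)

    def test_identical_outcomes_across_strata_give_null_logrank(self):
        # one cycle of times per stratum -> exchangeable outcomes
        times = np.tile(np.arange(1.0, 11.0), 3)
        events = np.tile(np.r_[np.ones(9, int), 0], 3)
        y = SurvivalOutcome(times, events)
        train_scores = np.repeat([0.0, 1.0, 2.0], 10)
        sig = _simple_signature([1.0])
        X = pd.DataFrame({"f0": train_scores})
        report = evaluate(sig, X, y, X, y)
        assert report.per_score["c_score"]["logrank_p_3group"] == pytest.approx(1.0)
        hr = report.per_score["c_score"]["hr_high_vs_low"]
        assert hr == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_signature_reports_half_cpe(self):
        X, y, _ = make_cox_instance(60, 2, seed=51)
        Xdf = pd.DataFrame(X, columns=["f0", "f1"])
        empty = Signature(features=(), betas=np.array([]), means=np.array([]),
                          scales=np.array([]))
        report = evaluate(empty, Xdf, y, Xdf, y)
        entry = report.per_score["c_score"]
        assert entry["degenerate"]
        assert entry["cpe_test"] == 0.5
        assert entry["logrank_p_3group"] == 1.0
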