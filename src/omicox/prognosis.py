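"""Signature application and prognostic evaluation.

A signature is the set of nonzero-coefficient features selected by the
penalized Cox path, together with the training standardization transform.
Two prognostic indices are derived per patient:

c-score
    The fitted linear predictor, sum_i x_i beta_i on standardized values.
t-score
    The difference between the mean of the poor-prognosis features
    (beta_i > 0) and the mean of the good-prognosis features
    (beta_i < 0), on standardized values.

Patients are stratified into low/intermediate/high risk at the training
tertiles of each index; cutoffs are applied to test cohorts verbatim and
never re-estimated. Patient-specific median time-to-event comes from the
Breslow baseline: the smallest observed event time t with
S(t|x) = exp(-H0(t) exp(eta)) <= 0.5, or "not reached" when the curve
stays above 0.5 throughout follow-up.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concordance import validation_cpe
from .survival import (
    StepFunction,
    as_outcome,
    hazard_ratio_wald,
    logrank_test,
)

__all__ = [
    "Signature",
    "RiskScores",
    "StrataAssignment",
    "PredictionReport",
    "compute_scores",
    "stratify",
    "predict_median_time",
    "evaluate",
]

logger = logging.getLogger(__name__)

STRATA = ("low", "intermediate", "high")


@dataclass(frozen=True)
class Signature:
    """Selected nonzero features with their coefficients and transform.

    ``betas`` are on the standardized scale; ``means``/``scales`` are the
    training standardization parameters, stored so test cohorts reuse
    them. Features with beta > 0 indicate poor prognosis (higher values,
    higher hazard), beta < 0 good prognosis.
    """

    features: tuple
    betas: np.ndarray
    means: np.ndarray
    scales: np.ndarray

    def __post_init__(self):
        betas = np.asarray(self.betas, float)
        if np.any(betas == 0):
            raise ValueError("signature coefficients must be nonzero")
        if not (len(self.features) == betas.shape[0] == len(self.means) == len(self.scales)):
            raise ValueError("signature fields must have equal lengths")
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "betas", betas)
        object.__setattr__(self, "means", np.asarray(self.means, float))
        object.__setattr__(self, "scales", np.asarray(self.scales, float))

    def __len__(self) -> int:
        return len(self.features)

    @property
    def directions(self) -> np.ndarray:
        """'poor' where beta > 0, 'good' where beta < 0."""
        return np.where(self.betas > 0, "poor", "good")

    @classmethod
    def from_cv_model(cls, model) -> "Signature":
        """Extract the signature from a fitted :class:`CoxLassoCV`."""
        nz = model.nonzero_
        names = [model.feature_names_[k] for k in nz]
        pm = model.path_model_
        return cls(
            features=tuple(names),
            betas=model.coef_[nz],
            means=pm.mean_[nz],
            scales=pm.scale_[nz],
        )

    def to_frame(self) -> pd.DataFrame:
        feats = list(self.features)
        platform = [f[0] if isinstance(f, tuple) else "" for f in feats]
        fid = [f[1] if isinstance(f, tuple) else f for f in feats]
        return pd.DataFrame(
            {"platform": platform, "feature": fid, "beta": self.betas,
             "mean": self.means, "scale": self.scales,
             "direction": self.directions}
        )


@dataclass(frozen=True)
class RiskScores:
    c_score: np.ndarray
    t_score: np.ndarray
    sample_ids: tuple


@dataclass(frozen=True)
class StrataAssignment:
    """Tertile cutoffs from training scores and the resulting labels."""

    cutoffs: tuple
    labels: np.ndarray


def _signature_matrix(signature: Signature, X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [f for f in signature.features if f not in X.columns]
        if missing:
            raise KeyError(f"signature features missing from X: {missing[:10]}")
        vals = X[list(signature.features)].to_numpy(dtype=float)
        ids = tuple(X.index)
    else:
        vals = np.asarray(X, dtype=float)
        if vals.shape[1] != len(signature):
            raise ValueError("X has the wrong number of signature features")
        ids = tuple(range(vals.shape[0]))
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values in signature features")
    return (vals - signature.means) / signature.scales, ids


def compute_scores(signature: Signature, X) -> RiskScores:
    """c-scores and t-scores of a cohort under a fitted signature.

    ``X`` holds raw feature values; standardization uses the training
    transform stored in the signature and is never refit.
    """
    Xs, ids = _signature_matrix(signature, X)
    c = Xs @ signature.betas
    poor = signature.betas > 0
    good = ~poor
    poor_mean = Xs[:, poor].mean(axis=1) if poor.any() else np.zeros(Xs.shape[0])
    good_mean = Xs[:, good].mean(axis=1) if good.any() else np.zeros(Xs.shape[0])
    return RiskScores(c_score=c, t_score=poor_mean - good_mean, sample_ids=ids)


def stratify(train_scores, test_scores=None) -> StrataAssignment:
    """Tertile stratification with training-derived cutoffs.

    Cutoffs are the 1/3 and 2/3 linear-interpolation quantiles of the
    training scores; a score equal to a cutoff goes to the lower stratum.
    The labels returned are for ``test_scores`` (defaulting to the
    training scores themselves).
    """
    train_scores = np.asarray(train_scores, float)
    if train_scores.shape[0] < 3:
        raise ValueError("tertile stratification needs at least three training scores")
    if np.ptp(train_scores) == 0:
        raise ValueError("all training scores identical; stratification is degenerate")
    c1, c2 = np.quantile(train_scores, [1 / 3, 2 / 3], method="linear")
    scores = train_scores if test_scores is None else np.asarray(test_scores, float)
    labels = np.where(scores <= c1, "low",
                      np.where(scores <= c2, "intermediate", "high"))
    return StrataAssignment(cutoffs=(float(c1), float(c2)), labels=labels)


def predict_median_time(baseline: StepFunction, eta):
    """Predicted median time-to-event per patient (months).

    S(t|x) = exp(-H0(t) * exp(eta)); returns the smallest knot t with
    S(t|x) <= 0.5 and NaN where the curve never crosses 0.5 within
    follow-up (not reached).
    """
    eta = np.atleast_1d(np.asarray(eta, float))
    # S <= 0.5  <=>  H0(t) >= log(2) * exp(-eta)
    threshold = np.log(2.0) * np.exp(-eta)
    if baseline.knots.size == 0:
        return np.full(eta.shape, np.nan)
    H = baseline.values
    idx = np.searchsorted(H, threshold, side="left")
    out = np.where(idx < baseline.knots.shape[0],
                   baseline.knots[np.minimum(idx, baseline.knots.shape[0] - 1)],
                   np.nan)
    return out


@dataclass
class PredictionReport:
    """Table-style evaluation of a signature on a withheld cohort.

    One entry per score type (c-score, t-score): tertile cutoffs,
    stratum sizes, 3-group and low-vs-high log-rank p-values, the
    high-vs-low hazard ratio with Wald 95% CI, and the test-cohort CPE.
    Plus per-patient predicted median times from the c-score.
    """

    per_score: dict
    median_times: pd.DataFrame
    n_train: int
    n_test: int
    signature_size: int

    def to_dict(self) -> dict:
        return {
            "per_score": self.per_score,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "signature_size": self.signature_size,
            "median_times": self.median_times.to_dict(orient="list"),
        }


def _evaluate_one_score(train_scores, test_scores, test_outcome):
    entry: dict = {}
    if np.ptp(np.asarray(train_scores, float)) == 0:
        # degenerate index (e.g. empty signature): no stratification possible
        entry.update({
            "cutoffs": None, "strata_sizes": None, "logrank_p_3group": 1.0,
            "logrank_p_low_vs_high": 1.0, "hr_high_vs_low": None, "hr_ci": None,
            "cpe_test": validation_cpe(np.asarray(test_scores, float), test_outcome),
            "degenerate": True,
        })
        return entry, None
    strata = stratify(train_scores, test_scores)
    entry["cutoffs"] = list(strata.cutoffs)
    labels = strata.labels
    sizes = {s: int((labels == s).sum()) for s in STRATA}
    entry["strata_sizes"] = sizes
    nonempty = [s for s in STRATA if sizes[s] > 0]
    if len(nonempty) >= 2:
        mask = np.isin(labels, nonempty)
        entry["logrank_p_3group"] = logrank_test(
            test_outcome.subset(mask), labels[mask]
        ).p
    else:
        logger.warning("fewer than two nonempty strata; log-rank p omitted")
        entry["logrank_p_3group"] = None
    lh = np.isin(labels, ["low", "high"])
    if sizes["low"] > 0 and sizes["high"] > 0:
        entry["logrank_p_low_vs_high"] = logrank_test(
            test_outcome.subset(lh), labels[lh]
        ).p
        try:
            hr, lo, hi = hazard_ratio_wald(
                (labels[lh] == "high").astype(float), test_outcome.subset(lh)
            )
            entry["hr_high_vs_low"] = hr
            entry["hr_ci"] = [lo, hi]
        except Exception as exc:  # separation etc.
            logger.warning("hazard-ratio fit failed: %s", exc)
            entry["hr_high_vs_low"] = None
            entry["hr_ci"] = None
    else:
        logger.warning("empty low or high stratum; HR omitted")
        entry["logrank_p_low_vs_high"] = None
        entry["hr_high_vs_low"] = None
        entry["hr_ci"] = None
    entry["cpe_test"] = validation_cpe(np.asarray(test_scores, float), test_outcome)
    entry["degenerate"] = False
    return entry, strata


def evaluate(signature: Signature, X_train, outcome_train, X_test, outcome_test,
             baseline: StepFunction | None = None) -> PredictionReport:
    """Full evaluation of a fitted signature on a withheld cohort.

    The signature must come from the training cohort only; evaluating on
    the training cohort itself is permitted for diagnostics but logged as
    a warning.
    """
    outcome_train = as_outcome(outcome_train)
    outcome_test = as_outcome(outcome_test)
    train_scores = compute_scores(signature, X_train)
    test_scores = compute_scores(signature, X_test)
    if len(outcome_train) == len(outcome_test) and np.array_equal(
        outcome_train.time, outcome_test.time
    ):
        logger.warning("test cohort appears identical to the training cohort")

    per_score = {}
    strata_by_score = {}
    for name, tr, te in (
        ("c_score", train_scores.c_score, test_scores.c_score),
        ("t_score", train_scores.t_score, test_scores.t_score),
    ):
        per_score[name], strata_by_score[name] = _evaluate_one_score(
            tr, te, outcome_test
        )

    if baseline is None:
        Xs_train, _ = _signature_matrix(signature, X_train)
        from .survival import breslow_baseline

        baseline = breslow_baseline(signature.betas, Xs_train, outcome_train)
    med = predict_median_time(baseline, test_scores.c_score)
    strata_c = strata_by_score.get("c_score")
    med_df = pd.DataFrame(
        {
            "sample_id": list(test_scores.sample_ids),
            "c_score": test_scores.c_score,
            "t_score": test_scores.t_score,
            "stratum": strata_c.labels if strata_c is not None else ["NA"] * len(med),
            "predicted_median_months": med,
            "not_reached": np.isnan(med),
        }
    )
    return PredictionReport(
        per_score=per_score,
        median_times=med_df,
        n_train=len(outcome_train),
        n_test=len(outcome_test),
        signature_size=len(signature),
    )
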