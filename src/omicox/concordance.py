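"""Concordance probability estimation.

The Gonen-Heller concordance probability estimate (CPE) measures the
discriminatory power of a Cox proportional hazards model from the fitted
linear predictors alone: under the model, the probability that of two
patients the one with the higher risk score fails first is a logistic
function of the score difference. A value of 0.5 indicates a random
prediction, 1.0 perfect discrimination.

Three entry points:

``cpe``
    The exact (and optionally smoothed) estimate, a function of the
    linear predictors only.
``harrell_c``
    Harrell's concordance index against observed right-censored outcomes
    (an independent, outcome-based concordance oracle; wraps
    scikit-survival).
``validation_cpe``
    The CPE of a prognostic index evaluated on held-out data. Because the
    raw estimate depends only on the spread of the index, it is anchored
    to the held-out outcomes by refitting a single Cox calibration
    coefficient before applying the formula; an index that carries no
    outcome information then scores ~0.5 regardless of its spread.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, ndtr

from .survival import (
    ConvergenceError,
    DegenerateDataError,
    as_outcome,
    fit_cox_unpenalized,
    neg_log_partial_likelihood,
)

__all__ = ["cpe", "default_bandwidth", "harrell_c", "validation_cpe"]


def _pair_diffs(eta: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(eta.shape[0], k=1)
    return eta[i] - eta[j]


def cpe(eta, h: float | None = None) -> float:
    """Gonen-Heller concordance probability estimate.

    Parameters
    ----------
    eta : per-sample linear predictors (risk scores) of a fitted Cox model.
    h : smoothing bandwidth. ``None`` (default) computes the exact form;
        a positive value replaces the pair indicator with the standard
        normal CDF ``Phi(-x_ij / h)``.

    Notes
    -----
    Exact form: each pair with distinct predictors contributes the
    logistic of the absolute score difference, i.e. the model-implied
    probability that the higher-risk patient fails first; tied pairs are
    uninformative and are excluded. If every pair is tied the model makes
    random predictions and the estimate is 0.5 by definition. The
    estimate depends only on the fitted model, never on observed times.
    """
    eta = np.asarray(eta, dtype=float).ravel()
    n = eta.shape[0]
    if n < 2:
        raise ValueError("CPE needs at least two samples")
    if not np.all(np.isfinite(eta)):
        raise ValueError("linear predictors must be finite")
    d = _pair_diffs(eta)
    if h is not None:
        if h <= 0:
            raise ValueError("smoothing bandwidth h must be positive")
        # smoothed form over ordered pairs, full denominator n(n-1)
        contrib = ndtr(-d / h) * expit(-d) + ndtr(d / h) * expit(d)
        return float(contrib.mean())
    informative = d != 0
    if not informative.any():
        return 0.5
    return float(expit(np.abs(d[informative])).mean())


def default_bandwidth(eta) -> float:
    """Reference smoothing rate 0.5 * sd(eta) * n^(-1/3)."""
    eta = np.asarray(eta, dtype=float).ravel()
    return 0.5 * float(eta.std()) * eta.shape[0] ** (-1.0 / 3.0)


def harrell_c(eta, outcome) -> float:
    """Harrell's concordance index of risk scores against observed outcomes.

    Fraction of usable pairs (earlier event vs. longer survivor) in which
    the higher score belongs to the shorter time; score ties count 1/2.
    """
    from sksurv.exceptions import NoComparablePairException
    from sksurv.metrics import concordance_index_censored

    outcome = as_outcome(outcome)
    eta = np.asarray(eta, dtype=float).ravel()
    if eta.shape[0] != len(outcome):
        raise ValueError("eta and outcome disagree on the number of samples")
    if eta.shape[0] < 2:
        raise ValueError("concordance needs at least two samples")
    try:
        cindex = concordance_index_censored(
            outcome.event.astype(bool), outcome.time, eta
        )[0]
    except NoComparablePairException as exc:
        raise ValueError("no usable pairs for Harrell's C") from exc
    return float(cindex)


_GAMMA_CAP = 50.0


def validation_cpe(eta, outcome) -> float:
    """CPE of a prognostic index on held-out data.

    Standardizes the index, refits the single Cox calibration coefficient
    gamma on the held-out outcomes, and returns ``cpe(gamma * eta_std)``.
    A constant index (e.g. the zero model at lambda_max) returns exactly
    0.5. If the calibration fit separates (monotone likelihood), gamma is
    capped; the estimate then approaches 1 as it should.
    """
    outcome = as_outcome(outcome)
    eta = np.asarray(eta, dtype=float).ravel()
    if eta.shape[0] != len(outcome):
        raise ValueError("eta and outcome disagree on the number of samples")
    sd = eta.std()
    if not np.isfinite(sd) or sd < 1e-12:
        return 0.5
    s = (eta - eta.mean()) / sd
    try:
        gamma = float(fit_cox_unpenalized(s[:, None], outcome).beta[0])
    except DegenerateDataError:
        return 0.5
    except ConvergenceError:
        _, g = neg_log_partial_likelihood(np.zeros(1), s[:, None], outcome)
        gamma = -np.sign(g[0]) * _GAMMA_CAP if g[0] != 0 else 0.0
    gamma = float(np.clip(gamma, -_GAMMA_CAP, _GAMMA_CAP))
    if gamma == 0.0:
        return 0.5
    return cpe(gamma * s)
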