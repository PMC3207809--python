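"""Survival-analysis primitives.

Right-censored outcomes, Kaplan-Meier product-limit curves, the k-sample
log-rank test, the Cox partial likelihood with Breslow handling of tied
event times, an unpenalized Newton Cox fitter, and the Breslow estimator
of the cumulative baseline hazard.

All times are in months. The Breslow convention is used consistently for
ties across the likelihood, the baseline estimator and the penalized path
solver so that the three agree on the same objective.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalOutcome",
    "StepFunction",
    "CoxFit",
    "LogrankResult",
    "ConvergenceError",
    "DegenerateDataError",
    "as_outcome",
    "neg_log_partial_likelihood",
    "fit_cox_unpenalized",
    "kaplan_meier",
    "logrank_test",
    "breslow_baseline",
]


class DegenerateDataError(ValueError):
    """Raised when an outcome cannot support the requested computation
    (e.g. fitting with no observed events)."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge, typically due to
    monotone likelihood / separation."""


@dataclass(frozen=True)
class SurvivalOutcome:
    """Right-censored follow-up.

    Parameters
    ----------
    time : array of positive, finite follow-up times (months).
    event : array of {0, 1}; 1 means the event was observed, 0 censored.
    """

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        if time.ndim != 1 or event.ndim != 1:
            raise ValueError("time and event must be one-dimensional")
        if time.shape[0] != event.shape[0]:
            raise ValueError(
                f"time has length {time.shape[0]} but event has length {event.shape[0]}"
            )
        if not np.all(np.isfinite(time)):
            raise ValueError("follow-up times must be finite")
        if np.any(time <= 0):
            raise ValueError("follow-up times must be positive")
        uniq = np.unique(event)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("event indicators must be 0 (censored) or 1 (event)")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(np.int8))

    def __len__(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx) -> "SurvivalOutcome":
        return SurvivalOutcome(self.time[idx], self.event[idx])

    def to_structured(self) -> np.ndarray:
        """Structured array with ``event``/``time`` fields (scikit-survival
        convention)."""
        out = np.empty(len(self), dtype=[("event", "?"), ("time", "<f8")])
        out["event"] = self.event.astype(bool)
        out["time"] = self.time
        return out


def as_outcome(y) -> SurvivalOutcome:
    """Coerce ``y`` into a :class:`SurvivalOutcome`.

    Accepts a SurvivalOutcome, a structured array with ``time``/``event``
    fields, or a ``(time, event)`` pair.
    """
    if isinstance(y, SurvivalOutcome):
        return y
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = set(y.dtype.names)
        if {"time", "event"} <= names:
            return SurvivalOutcome(y["time"], y["event"].astype(int))
    if isinstance(y, (tuple, list)) and len(y) == 2:
        return SurvivalOutcome(np.asarray(y[0]), np.asarray(y[1]))
    raise TypeError(
        "expected SurvivalOutcome, structured array with 'time'/'event' fields, "
        "or a (time, event) pair"
    )


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous step function.

    ``initial`` is the value before the first knot (1.0 for survival
    curves, 0.0 for cumulative hazards); ``values[k]`` is the value on
    ``[knots[k], knots[k+1])``.
    """

    knots: np.ndarray
    values: np.ndarray
    initial: float = 1.0

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if knots.shape != values.shape or knots.ndim != 1:
            raise ValueError("knots and values must be 1-d arrays of equal length")
        if knots.size and np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "values", values)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t, side="right")
        padded = np.concatenate([[self.initial], self.values])
        out = padded[idx]
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class CoxFit:
    """Unpenalized Cox proportional hazards fit."""

    beta: np.ndarray
    standard_errors: np.ndarray
    log_partial_likelihood: float
    n_iter: int
    covariance: np.ndarray


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# Partial likelihood internals (Breslow ties)
# ---------------------------------------------------------------------------


def _breslow_parts(eta, time, event):
    """Negative log partial likelihood plus its per-sample derivatives.

    Returns ``(nll, u, w)`` where ``u = d log L / d eta`` and ``w`` is the
    diagonal of minus the second derivative with respect to ``eta`` in the
    usual glmnet-Cox diagonal approximation.
    """
    eta = np.asarray(eta, dtype=float)
    n = eta.shape[0]
    order = np.argsort(time, kind="mergesort")
    t_s = time[order]
    d_s = event[order].astype(float)
    eta_s = eta[order]
    m = eta_s.max() if n else 0.0
    ex = np.exp(eta_s - m)

    # suffix sums: risk-set mass at each sorted position
    suffix = np.cumsum(ex[::-1])[::-1]

    # unique-time groups; risk set for a group starts at its first index
    starts = np.flatnonzero(np.concatenate([[True], t_s[1:] != t_s[:-1]]))
    counts = np.diff(np.concatenate([starts, [n]]))
    group_of = np.repeat(np.arange(starts.size), counts)
    d_g = np.add.reduceat(d_s, starts)
    S_g = suffix[starts]

    with np.errstate(divide="ignore"):
        log_S = np.log(S_g)
    nll = -float(eta_s[d_s > 0].sum()) + float((d_g * (log_S + m)).sum())

    # cumulative hazard increments experienced by each sample: sum over
    # event groups with group time <= y_i  (sample is in those risk sets)
    a_inc = np.where(S_g > 0, d_g / S_g, 0.0)
    b_inc = np.where(S_g > 0, d_g / S_g**2, 0.0)
    A_g = np.cumsum(a_inc)
    B_g = np.cumsum(b_inc)
    A_i = A_g[group_of]
    B_i = B_g[group_of]

    u_s = d_s - ex * A_i
    w_s = ex * A_i - ex**2 * B_i

    u = np.empty(n)
    w = np.empty(n)
    u[order] = u_s
    w[order] = w_s
    return nll, u, w


def neg_log_partial_likelihood(beta, X, outcome):
    """Negative log Cox partial likelihood and its gradient.

    Implements -log prod_{i: event} exp(x_i' beta) / sum_{j in R_i}
    exp(x_j' beta) with Breslow handling of tied times.

    Returns
    -------
    (value, gradient)
    """
    outcome = as_outcome(outcome)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-d matrix (samples x features)")
    if X.shape[0] != len(outcome):
        raise ValueError("X and outcome disagree on the number of samples")
    if X.shape[1] != beta.shape[0]:
        raise ValueError("beta length does not match the number of features")
    if outcome.n_events == 0:
        raise DegenerateDataError("all samples are censored; the partial likelihood is flat")
    eta = X @ beta
    nll, u, _ = _breslow_parts(eta, outcome.time, outcome.event)
    grad = -(X.T @ u)
    return nll, grad


def _cox_information(eta, X, time, event):
    """Observed information (negative Hessian of log L) w.r.t. beta."""
    n, p = X.shape
    order = np.argsort(time, kind="mergesort")
    t_s = time[order]
    d_s = event[order].astype(float)
    Xo = X[order]
    m = eta.max()
    ex = np.exp(eta[order] - m)

    # suffix sums over risk sets (samples with y >= t)
    S0 = np.cumsum(ex[::-1])[::-1]
    S1 = np.cumsum((ex[:, None] * Xo)[::-1], axis=0)[::-1]
    XX = Xo[:, :, None] * Xo[:, None, :]
    S2 = np.cumsum((ex[:, None, None] * XX)[::-1], axis=0)[::-1]

    starts = np.flatnonzero(np.concatenate([[True], t_s[1:] != t_s[:-1]]))
    d_g = np.add.reduceat(d_s, starts)
    keep = d_g > 0
    g0 = S0[starts][keep]
    g1 = S1[starts][keep]
    g2 = S2[starts][keep]
    d = d_g[keep]
    mu = g1 / g0[:, None]
    H = np.einsum("g,gij->ij", d, g2 / g0[:, None, None])
    H -= np.einsum("g,gi,gj->ij", d, mu, mu)
    return H


def fit_cox_unpenalized(X, outcome, tol: float = 1e-8, max_iter: int = 100) -> CoxFit:
    """Newton-Raphson fit of the Cox model on the Breslow partial likelihood.

    Iterates to gradient sup-norm <= ``tol``; standard errors come from the
    inverse observed information. Monotone likelihood (separation) and
    other non-convergence is reported via :class:`ConvergenceError`.
    """
    outcome = as_outcome(outcome)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if outcome.n_events == 0:
        raise DegenerateDataError("cannot fit a Cox model with no observed events")
    if p > n:
        raise ValueError("more features than samples; use the penalized path instead")
    if np.any(X.std(axis=0) <= 1e-12):
        raise ValueError("constant columns are unidentifiable under the partial likelihood")

    beta = np.zeros(p)
    nll, grad = neg_log_partial_likelihood(beta, X, outcome)
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) <= tol:
            if np.max(np.abs(beta) * X.std(axis=0)) > 15.0:
                # gradient vanished only because the likelihood is monotone
                raise ConvergenceError(
                    "implausibly large standardized effect; monotone likelihood "
                    "(separation) suspected"
                )
            H = _cox_information(X @ beta, X, outcome.time, outcome.event)
            cov = np.linalg.inv(H)
            se = np.sqrt(np.diag(cov))
            return CoxFit(beta, se, -nll, it - 1, cov)
        H = _cox_information(X @ beta, X, outcome.time, outcome.event)
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError as exc:  # singular information
            raise ConvergenceError(
                "singular information matrix; likely separation or collinearity"
            ) from exc
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            nll_new, grad_new = neg_log_partial_likelihood(cand, X, outcome)
            if nll_new <= nll + 1e-12:
                break
            t *= 0.5
        else:
            raise ConvergenceError("step halving failed to decrease the objective")
        beta, nll, grad = cand, nll_new, grad_new
        if np.max(np.abs(beta)) > 1e3:
            raise ConvergenceError(
                "coefficients diverging; monotone likelihood (separation) suspected"
            )
    raise ConvergenceError(f"Newton iteration did not converge in {max_iter} steps")


# ---------------------------------------------------------------------------
# Nonparametric estimators
# ---------------------------------------------------------------------------


def kaplan_meier(outcome) -> StepFunction:
    """Product-limit estimate of the survival function.

    The returned step function drops only at observed event times; with no
    events it is the constant function 1.
    """
    outcome = as_outcome(outcome)
    if len(outcome) == 0:
        raise ValueError("empty outcome")
    time, event = outcome.time, outcome.event
    order = np.argsort(time, kind="mergesort")
    t_s, d_s = time[order], event[order].astype(float)
    n = len(outcome)
    starts = np.flatnonzero(np.concatenate([[True], t_s[1:] != t_s[:-1]]))
    counts = np.diff(np.concatenate([starts, [n]]))
    d_g = np.add.reduceat(d_s, starts)
    at_risk = n - starts  # samples with y >= group time
    keep = d_g > 0
    knots = t_s[starts][keep]
    surv = np.cumprod(1.0 - d_g[keep] / at_risk[keep])
    return StepFunction(knots, surv, initial=1.0)


def logrank_test(outcome, groups) -> LogrankResult:
    """k-sample log-rank test (chi-square with k-1 df).

    Backed by ``lifelines.statistics.multivariate_logrank_test``; a group
    with zero members is an error.
    """
    from lifelines.statistics import multivariate_logrank_test

    outcome = as_outcome(outcome)
    groups = np.asarray(groups)
    if groups.shape[0] != len(outcome):
        raise ValueError("groups and outcome disagree on the number of samples")
    levels, counts = np.unique(groups, return_counts=True)
    if levels.size < 2:
        raise ValueError("log-rank test needs at least two groups")
    if np.any(counts == 0):
        raise ValueError("every group must be nonempty")
    res = multivariate_logrank_test(outcome.time, groups, outcome.event)
    chi2 = float(res.test_statistic)
    df = int(levels.size - 1)
    p = float(stats.chi2.sf(chi2, df))
    return LogrankResult(chi2=chi2, df=df, p=p)


def breslow_baseline(beta, X, outcome) -> StepFunction:
    """Breslow estimator of the cumulative baseline hazard H0.

    H0(t) = sum_{event times t_i <= t} d_i / sum_{j in R_i} exp(x_j' beta).
    At beta = 0 the increments are d_i / |R_i| (Nelson-Aalen).
    """
    outcome = as_outcome(outcome)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    eta = X @ beta
    time, event = outcome.time, outcome.event
    n = len(outcome)
    order = np.argsort(time, kind="mergesort")
    t_s, d_s = time[order], event[order].astype(float)
    m = eta.max() if n else 0.0
    ex = np.exp(eta[order] - m)
    suffix = np.cumsum(ex[::-1])[::-1]
    starts = np.flatnonzero(np.concatenate([[True], t_s[1:] != t_s[:-1]]))
    d_g = np.add.reduceat(d_s, starts)
    S_g = suffix[starts] * np.exp(m)
    keep = d_g > 0
    knots = t_s[starts][keep]
    H0 = np.cumsum(d_g[keep] / S_g[keep])
    return StepFunction(knots, H0, initial=0.0)


def hazard_ratio_wald(indicator, outcome):
    """Hazard ratio with Wald 95% CI from a single binary-covariate Cox fit.

    Returns ``(hr, lo, hi)``; the covariate codes the comparison group as 1.
    """
    fit = fit_cox_unpenalized(np.asarray(indicator, float)[:, None], outcome)
    b = float(fit.beta[0])
    se = float(fit.standard_errors[0])
    with np.errstate(over="ignore"):  # huge se -> infinite upper CI is legitimate
        return (float(np.exp(b)), float(np.exp(b - 1.96 * se)),
                float(np.exp(b + 1.96 * se)))
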