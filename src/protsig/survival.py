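"""Survival analysis: Kaplan-Meier, log-rank, Cox PH, interaction LRT.

The Cox model maximizes the Efron-approximation partial likelihood by Newton
iterations with step-halving, reporting per-covariate Wald statistics
(HR = exp(coef), 95% CI = exp(coef +/- 1.96*SE)) and the log partial
likelihood; the treatment-interaction test is a likelihood-ratio comparison
of nested Cox models with and without a treatment x score product term
(chi-square, 1 df).  Tied event and censoring times are resolved events-first
(censored subjects at time t remain at risk for events at t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConvergenceError, DegenerateDataError, ValidationError

_Z975 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival estimate, defined at observed event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_time_event(time, event):
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event, dtype=float).ravel()
    if len(time) != len(event):
        raise ValidationError("time and event must have equal length")
    if len(time) == 0:
        raise ValidationError("no subjects")
    if (time < 0).any():
        raise ValidationError("negative survival time")
    if not np.isin(event, (0, 1)).all():
        raise ValidationError("event indicator must be 0 or 1")
    return time, event.astype(int)


def kaplan_meier(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    At each observed event time t with d events among n at risk the
    survival is multiplied by (1 - d/n); censored subjects leave the risk
    set after their time (ties: events first).
    """
    time, event = _check_time_event(time, event)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    unique_times, start_idx = np.unique(time, return_index=True)
    n = len(time)
    at_risk_all = n - start_idx  # everyone with t >= unique time
    d_all = np.add.reduceat(event, start_idx)
    has_event = d_all > 0
    factors = 1.0 - d_all[has_event] / at_risk_all[has_event]
    return KMCurve(
        event_times=unique_times[has_event],
        survival=np.cumprod(factors),
        at_risk=at_risk_all[has_event].astype(int),
        n_events=d_all[has_event].astype(int),
        censor_times=np.sort(time[event == 0]),
    )


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


def log_rank(time, event, group) -> LogRankResult:
    """Two-group log-rank test.

    At every event time the observed events in group 1 are compared with the
    hypergeometric expectation given the margins; chi2 = (sum(O1-E1))^2 /
    sum(V) on 1 df.
    """
    time, event = _check_time_event(time, event)
    group = np.asarray(group).ravel()
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValidationError(f"log_rank needs exactly two groups, got {len(levels)}")
    g1 = group == levels[1]
    if event.sum() == 0:
        raise ValidationError("log_rank needs at least one event")
    order = np.argsort(time, kind="stable")
    time, event, g1 = time[order], event[order], g1[order]
    unique_times, start_idx = np.unique(time, return_index=True)
    n = len(time)
    n_at_risk = n - start_idx
    n1_at_risk = np.cumsum(g1[::-1])[::-1][start_idx]
    d = np.add.reduceat(event, start_idx)
    d1 = np.add.reduceat(event * g1, start_idx)
    mask = d > 0
    n_t, n1_t, d_t, d1_t = n_at_risk[mask], n1_at_risk[mask], d[mask], d1[mask]
    e1 = d_t * n1_t / n_t
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / np.maximum(n_t - 1, 1)
    v = np.where(n_t > 1, v, 0.0)
    total_v = v.sum()
    if total_v == 0:
        return LogRankResult(0.0, 1, 1.0)
    chi2 = float((d1_t - e1).sum() ** 2 / total_v)
    return LogRankResult(chi2, 1, float(stats.chi2.sf(chi2, 1)))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties, Newton-Raphson)
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Results of a Cox proportional-hazards fit."""

    coefficients: pd.Series
    standard_errors: pd.Series
    log_likelihood: float
    n: int
    n_events: int
    converged: bool
    ties: str = "efron"
    covariance: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coefficients).rename("HR")

    @property
    def confidence_intervals(self) -> pd.DataFrame:
        lo = np.exp(self.coefficients - _Z975 * self.standard_errors)
        hi = np.exp(self.coefficients + _Z975 * self.standard_errors)
        return pd.DataFrame({"HR_lower_95": lo, "HR_upper_95": hi})

    @property
    def p_values(self) -> pd.Series:
        z = self.coefficients / self.standard_errors
        return pd.Series(
            2 * stats.norm.sf(np.abs(z)), index=self.coefficients.index, name="p"
        )

    def summary(self) -> pd.DataFrame:
        """Per-covariate coef, HR, Wald 95% CI and p, Table-style."""
        out = pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hazard_ratios,
                "se": self.standard_errors,
            }
        )
        out = out.join(self.confidence_intervals)
        out["p"] = self.p_values
        return out


def _efron_loglik_grad_hess(beta, time, event, X, ties="efron"):
    """Log partial likelihood, gradient and Hessian at beta (sorted input).

    ``time`` must be ascending; risk sums are reverse cumulative sums.
    """
    n, p = X.shape
    eta = X @ beta
    # A constant shift of eta leaves ll, grad and hess exactly unchanged
    # (there is one log phi0 term per event, so the shifts cancel); use it
    # to keep exp() from overflowing.
    eta = eta - eta.max()
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    _, start_of_group, inverse = np.unique(time, return_index=True, return_inverse=True)
    d_per_group = np.bincount(inverse, weights=event).astype(int)
    ev_rows = np.flatnonzero(event == 1)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))

    # untied event times (Efron == Breslow for a single event): vectorized
    idx1 = ev_rows[d_per_group[inverse[ev_rows]] == 1]
    if len(idx1):
        gs = start_of_group[inverse[idx1]]
        s0 = S0[gs]
        z = S1[gs] / s0[:, None]
        ll += eta[idx1].sum() - np.log(s0).sum()
        grad += X[idx1].sum(axis=0) - z.sum(axis=0)
        hess -= (S2[gs] / s0[:, None, None]).sum(axis=0) - z.T @ z

    # tied event times: per-group loop
    for g in np.flatnonzero(d_per_group > 1):
        s = start_of_group[g]
        tie_idx = ev_rows[inverse[ev_rows] == g]
        d = len(tie_idx)
        s0r, s1r, s2r = S0[s], S1[s], S2[s]
        xt, wt = X[tie_idx], w[tie_idx]
        ll += eta[tie_idx].sum()
        grad += xt.sum(axis=0)
        if ties == "efron":
            s0t = wt.sum()
            s1t = (wt[:, None] * xt).sum(axis=0)
            s2t = (wt[:, None, None] * xt[:, :, None] * xt[:, None, :]).sum(axis=0)
            fracs = np.arange(d) / d
        else:  # breslow
            s0t, s1t, s2t = 0.0, 0.0, 0.0
            fracs = np.zeros(d)
        for f in fracs:
            phi0 = s0r - f * s0t
            phi1 = s1r - f * s1t
            phi2 = s2r - f * s2t
            ll -= np.log(phi0)
            z = phi1 / phi0
            grad -= z
            hess -= phi2 / phi0 - np.outer(z, z)
    return ll, grad, hess


def cox_fit(time, event, covariates, ties: str = "efron", max_iter: int = 100, tol: float = 1e-9) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Parameters
    ----------
    time, event : array-like
        Right-censored endpoint (event=1 observed, 0 censored).
    covariates : DataFrame or 2-D array
        One column per covariate; must be non-constant.
    ties : {"efron", "breslow"}
        Tied-event handling; Efron is the default and the more accurate.

    Raises
    ------
    ValidationError
        No events, or a constant covariate (named in the message).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] == 1 and X.size > X.shape[1]:
            X = X.T
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    time, event = _check_time_event(time, event)
    if X.shape[0] != len(time):
        raise ValidationError("covariate rows must match number of subjects")
    if np.isnan(X).any():
        raise ValidationError("missing covariate values; drop or impute upstream")
    if event.sum() == 0:
        raise ValidationError("cox_fit needs at least one event")
    sds = X.std(axis=0)
    for j, sd in enumerate(sds):
        if sd == 0:
            raise ValidationError(f"constant covariate: {names[j]}")

    # center and scale for numerical conditioning; transform back afterwards
    mu, sc = X.mean(axis=0), sds
    Xs = (X - mu) / sc

    order = np.argsort(time, kind="stable")
    t_s, e_s, X_s = time[order], event[order], Xs[order]

    beta = np.zeros(X.shape[1])
    ll, grad, hess = _efron_loglik_grad_hess(beta, t_s, e_s, X_s, ties)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving to keep the likelihood increasing
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            ll_new, grad_new, hess_new = _efron_loglik_grad_hess(cand, t_s, e_s, X_s, ties)
            if ll_new >= ll - 1e-12:
                break
            alpha /= 2.0
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 200:  # monotone likelihood / separation
            break

    # With a monotone partial likelihood the gradient also falls below tol on
    # the plateau; a scaled coefficient this large (HR > e^10 per SD) means
    # the maximum is at infinity, not a finite estimate.
    if converged and np.max(np.abs(beta)) > 10:
        converged = False
    if not converged:
        warnings.warn(
            "cox_fit did not converge (possible monotone likelihood / perfect "
            "separation); coefficients are reported but unreliable",
            UserWarning,
            stacklevel=2,
        )
    try:
        cov_s = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov_s = np.full((X.shape[1],) * 2, np.nan)
    # back-transform from the scaled covariates
    coefs = beta / sc
    cov = cov_s / np.outer(sc, sc)
    se = np.sqrt(np.diag(cov))
    return CoxFit(
        coefficients=pd.Series(coefs, index=names, name="coef"),
        standard_errors=pd.Series(se, index=names, name="se"),
        log_likelihood=float(ll),
        n=len(time),
        n_events=int(event.sum()),
        converged=converged,
        ties=ties,
        covariance=cov,
    )


def cox_partial_loglik(time, event, covariates, beta, ties: str = "efron") -> Tuple[float, np.ndarray]:
    """Log partial likelihood and its gradient at given coefficients.

    Exposed so the score equation can be checked directly at a fit.
    """
    if isinstance(covariates, pd.DataFrame):
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    time, event = _check_time_event(time, event)
    beta = np.asarray(beta, dtype=float).ravel()
    order = np.argsort(time, kind="stable")
    ll, grad, _ = _efron_loglik_grad_hess(beta, time[order], event[order], X[order], ties)
    return float(ll), grad


# ---------------------------------------------------------------------------
# Treatment x score interaction, likelihood-ratio test
# ---------------------------------------------------------------------------

def interaction_lrt(
    time,
    event,
    score,
    treatment,
    covariates: Optional[pd.DataFrame] = None,
    ties: str = "efron",
) -> Tuple[float, float, CoxFit, CoxFit]:
    """Likelihood-ratio test for a treatment x score interaction.

    Full model:    treatment + score + treatment:score (+ covariates)
    Reduced model: treatment + score (+ covariates)

    The statistic 2*(ll_full - ll_reduced) is referred to chi-square with
    1 df.  The score may be continuous or dichotomized (0/1).

    Returns
    -------
    (lrt_statistic, p_value, full_fit, reduced_fit)
    """
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event, dtype=float).ravel()
    score = np.asarray(score, dtype=float).ravel()
    treatment = np.asarray(treatment, dtype=float).ravel()
    if not np.isin(treatment, (0, 1)).all():
        raise ValidationError("treatment must be binary 0/1")
    for arm in (0, 1):
        if event[treatment == arm].sum() == 0:
            raise ValidationError(f"treatment arm {arm} has no events")
    base = pd.DataFrame({"treatment": treatment, "score": score})
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        base = pd.concat([base, covariates], axis=1)
    full = base.copy()
    full.insert(2, "treatment_x_score", treatment * score)
    fit_reduced = cox_fit(time, event, base, ties=ties)
    fit_full = cox_fit(time, event, full, ties=ties)
    if not (fit_full.converged and fit_reduced.converged):
        err = ConvergenceError("interaction_lrt: a Cox model did not converge")
        err.full = fit_full
        err.reduced = fit_reduced
        raise err
    stat = max(0.0, 2.0 * (fit_full.log_likelihood - fit_reduced.log_likelihood))
    p = float(stats.chi2.sf(stat, 1))
    return stat, p, fit_full, fit_reduced
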