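"""Survival and prognostic-value statistics: KM, log-rank, Cox, ROC.

The primary endpoint is five-year disease-free survival: time to recurrence
in months, administratively censored at 60.  Kaplan-Meier estimation and
the multi-group log-rank test are delegated to lifelines; the Cox
proportional-hazards fit is implemented here by Newton maximisation of the
partial likelihood with Breslow tie handling (the convention of classical
clinical-statistics software; Efron is available as an option), because the
tie convention changes hazard ratios when event times are coarsely
recorded.  ROC analysis reports the Mann-Whitney AUC with the
Hanley-McNeil standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import (
    ConvergenceError,
    InvalidParameterError,
    NoSignalError,
    SeparationError,
    ValidationError,
)

__all__ = [
    "KMCurve",
    "LogrankResult",
    "CoxFit",
    "ROCResult",
    "km_fit",
    "logrank_test",
    "two_group_logrank_chi2",
    "cox_fit",
    "roc_auc",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve: S(t) after each distinct event time.

    ``times`` starts at 0 with survival 1; ``at_risk`` is the risk-set size
    just before each time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    df: int
    p: float


@dataclass(frozen=True)
class CoxFit:
    """Cox proportional-hazards fit: one row of statistics per covariate."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    log_likelihood: float
    ties: str

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy per-factor table (factor, HR, CI bounds, p)."""
        return pd.DataFrame(
            {
                "factor": self.names,
                "coef": self.coef,
                "hr": self.hazard_ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            }
        )


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci: tuple[float, float]
    p: float
    n_cases: int
    n_controls: int


def _as_surv_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape or times.ndim != 1:
        raise ValidationError("times and events must be equal-length 1-d vectors")
    if np.any(times <= 0):
        raise ValidationError("survival times must be positive")
    if not np.all(np.isin(events, (0, 1))):
        raise ValidationError("event flags must be 0 or 1")
    return times, events


def km_fit(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Subjects censored at t are still counted at risk at t (the standard
    convention), so a censoring tied with an event does not dilute that
    event's factor.
    """
    times, events = _as_surv_arrays(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    event_times = event_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"]
    survival = np.array([float(surv.loc[t]) for t in event_times])
    at_risk = event_rows["at_risk"].to_numpy(dtype=float)
    return KMCurve(
        times=np.concatenate([[0.0], event_times]),
        survival=np.concatenate([[1.0], survival]),
        at_risk=np.concatenate([[float(len(times))], at_risk]),
    )


def logrank_test(times, events, groups) -> LogrankResult:
    """Multi-group log-rank test (O-E with hypergeometric variance, ties pooled)."""
    times, events = _as_surv_arrays(times, events)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValidationError("log-rank test needs at least two non-empty groups")
    if events.sum() == 0:
        raise NoSignalError("no events observed; log-rank statistic undefined")
    result = multivariate_logrank_test(times, groups, events)
    return LogrankResult(
        chi_square=float(result.test_statistic),
        df=len(labels) - 1,
        p=float(result.p_value),
    )


def two_group_logrank_chi2(times, events, in_group_one) -> float:
    """Vectorized two-group log-rank chi-square (df = 1).

    The square of the standardized O-E score; used heavily by the
    cut-point scan and by permutation references, hence kept allocation-light.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    g1 = np.asarray(in_group_one, dtype=bool)
    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], g1[order]
    ut = np.unique(t[e])
    if ut.size == 0:
        return 0.0
    first = np.searchsorted(t, ut, side="left")
    n_total = len(t) - first
    suffix_g1 = np.concatenate([np.cumsum(g[::-1])[::-1], [0]])
    n1 = suffix_g1[first]
    te = t[e]
    d = np.searchsorted(te, ut, side="right") - np.searchsorted(te, ut, side="left")
    te1 = t[e & g]
    d1 = np.searchsorted(te1, ut, side="right") - np.searchsorted(te1, ut, side="left")
    frac = n1 / n_total
    observed_minus_expected = float(np.sum(d1 - d * frac))
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = d * frac * (1.0 - frac) * (n_total - d) / (n_total - 1.0)
    variance = float(np.sum(var_terms[n_total > 1]))
    if variance <= 0:
        return 0.0
    return observed_minus_expected**2 / variance


def _partial_loglik_terms(beta, X, w_times, w_events, ties):
    """Breslow/Efron partial log-likelihood, gradient and information."""
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # rescaling cancels in all ratios; guards overflow
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    # suffix (risk-set) sums over time-ascending order
    c0 = np.cumsum(w[::-1])[::-1]
    c1 = np.cumsum(wx[::-1], axis=0)[::-1]
    c2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll, grad, info = 0.0, np.zeros(p), np.zeros((p, p))
    ut = np.unique(w_times[w_events])
    for t_k in ut:
        first = np.searchsorted(w_times, t_k, side="left")
        dead = w_events & (w_times == t_k)
        d = int(dead.sum())
        s0, s1, s2 = c0[first], c1[first], c2[first]
        ll += float(eta[dead].sum())
        grad += X[dead].sum(axis=0)
        if ties == "breslow":
            ll -= d * np.log(s0)
            grad -= d * s1 / s0
            info += d * (s2 / s0 - np.outer(s1, s1) / s0**2)
        else:  # efron
            t0 = float(w[dead].sum())
            t1 = wx[dead].sum(axis=0)
            t2 = wxx[dead].sum(axis=0)
            for j in range(d):
                f = j / d
                s0j = s0 - f * t0
                s1j = s1 - f * t1
                s2j = s2 - f * t2
                ll -= np.log(s0j)
                grad -= s1j / s0j
                info += s2j / s0j - np.outer(s1j, s1j) / s0j**2
    return ll, grad, info


def cox_fit(
    design: pd.DataFrame | np.ndarray,
    times,
    events,
    ties: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxFit:
    """Cox proportional-hazards regression by Newton iteration.

    ``design`` is the covariate table (n x p); columns must not be
    constant.  Convergence is declared at gradient norm < ``tol``; Wald
    95% confidence intervals use the 1.96 normal quantile.  A coefficient
    diverging towards +-infinity (monotone likelihood, i.e. a covariate
    that perfectly separates event order) raises :class:`SeparationError`
    rather than returning a spurious finite estimate.
    """
    if ties not in ("breslow", "efron"):
        raise InvalidParameterError("ties must be 'breslow' or 'efron'")
    times, events = _as_surv_arrays(times, events)
    if isinstance(design, pd.DataFrame):
        names = tuple(str(c) for c in design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    if X.shape[0] != len(times):
        raise ValidationError("design and survival vectors differ in length")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValidationError("constant covariate in the design matrix")
    n_events = int(events.sum())
    if n_events == 0:
        raise NoSignalError("no events; the partial likelihood is constant")
    if n_events < X.shape[1]:
        import warnings

        warnings.warn(
            f"{n_events} events for {X.shape[1]} covariates; estimates unstable",
            stacklevel=2,
        )

    # center covariates for numerical stability (shifts cancel in the
    # partial likelihood, coefficients are unaffected)
    center = X.mean(axis=0)
    Xc = X - center
    x_scale = Xc.std(axis=0)
    order = np.argsort(times, kind="stable")
    Xs = Xc[order]
    ts = times[order]
    es = events[order].astype(bool)

    beta = np.zeros(X.shape[1])
    ll, grad, info = _partial_loglik_terms(beta, Xs, ts, es, ties)
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        # step-halving keeps the likelihood non-decreasing (slack is relative:
        # round-off in the log-likelihood scales with its magnitude)
        slack = 1e-10 * (abs(ll) + 1.0)
        factor = 1.0
        for _half in range(30):
            candidate = beta + factor * step
            ll_new, grad_new, info_new = _partial_loglik_terms(candidate, Xs, ts, es, ties)
            if ll_new >= ll - slack:
                break
            factor /= 2.0
        beta, ll, grad, info = candidate, ll_new, grad_new, info_new
        # a per-SD log hazard ratio beyond ~15 only arises when the partial
        # likelihood is monotone (perfect separation of event order)
        if np.any(np.abs(beta) * x_scale > 15):
            raise SeparationError(
                "monotone partial likelihood: a covariate perfectly separates outcomes"
            )
    else:
        raise ConvergenceError(f"Cox fit did not converge in {max_iter} iterations")

    covariance = np.linalg.inv(info)
    se = np.sqrt(np.diag(covariance))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(
        names=names,
        coef=beta,
        se=se,
        hazard_ratio=np.exp(beta),
        ci_low=np.exp(beta - 1.96 * se),
        ci_high=np.exp(beta + 1.96 * se),
        p=p,
        log_likelihood=float(ll),
        ties=ties,
    )


def roc_auc(predictor, outcome) -> ROCResult:
    """Mann-Whitney AUC with Hanley-McNeil confidence interval.

    ``outcome`` is 1 for cases (recurrence) and 0 for controls; tied
    predictor values contribute 1/2.  The p-value tests AUC = 0.5 by a
    normal approximation with the Hanley-McNeil standard error.
    """
    predictor = np.asarray(predictor, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if predictor.shape != outcome.shape or predictor.ndim != 1:
        raise ValidationError("predictor and outcome must be equal-length vectors")
    n_cases = int(outcome.sum())
    n_controls = int(len(outcome) - n_cases)
    if n_cases == 0 or n_controls == 0:
        raise ValidationError("ROC needs both outcome classes present")
    auc = float(roc_auc_score(outcome, predictor))
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    variance = (
        auc * (1.0 - auc)
        + (n_cases - 1) * (q1 - auc**2)
        + (n_controls - 1) * (q2 - auc**2)
    ) / (n_cases * n_controls)
    se = float(np.sqrt(max(variance, 0.0)))
    if se == 0.0:
        p = 0.0 if auc != 0.5 else 1.0
    else:
        p = float(2.0 * stats.norm.sf(abs(auc - 0.5) / se))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    return ROCResult(auc=auc, ci=ci, p=p, n_cases=n_cases, n_controls=n_controls)
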