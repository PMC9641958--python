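"""Cox partial-likelihood machinery on counting-process data.

Implements the estimation layer the landmark super-model is built on:

* Newton-Raphson maximisation of the Breslow-ties log partial likelihood
  with delayed entry — a row is at risk at time ``t`` iff
  ``entry < t <= exit`` — which is exactly what stacked landmark rows need,
  since each row enters the risk set at its landmark time.
* Breslow baseline cumulative-hazard increments
  ``dH0(t_j) = d_j / sum_{risk set} exp(lp_i)``.
* A cluster-robust (sandwich) covariance with subjects as clusters, because
  one subject contributes up to one correlated row per landmark.
* Kaplan-Meier estimation with Greenwood variance and log(-log)-scale
  confidence intervals.

Breslow tie handling is used throughout: it keeps the likelihood, the
baseline estimator and the replicated-rows invariance mutually consistent,
which matters because the same failure time reappears at every landmark a
subject is at risk for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge within the iteration budget."""


@dataclass
class BaselineHazard:
    """Breslow baseline cumulative-hazard increments at distinct event times."""

    event_times: np.ndarray
    increments: np.ndarray

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.increments)

    def cumulative_at(self, t: float | np.ndarray) -> np.ndarray | float:
        """H0(t) = sum of increments at event times <= t (0 before the first)."""
        idx = np.searchsorted(self.event_times, np.asarray(t), side="right")
        cum = np.concatenate([[0.0], self.cumulative])
        return cum[idx]

    def window_hazard(self, start: float, stop: float) -> float:
        """Integrated baseline hazard over the half-open window (start, stop]."""
        return float(self.cumulative_at(stop) - self.cumulative_at(start))


@dataclass
class CoxFit:
    """A converged partial-likelihood fit on (entry, exit, status) rows."""

    coefficients: np.ndarray
    model_covariance: np.ndarray
    robust_covariance: np.ndarray
    log_partial_likelihood: float
    n_iterations: int
    final_gradient_norm: float
    design_column_names: list[str]

    @property
    def model_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.model_covariance))

    @property
    def robust_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.robust_covariance))

    def p_values(self, robust: bool = True) -> np.ndarray:
        """Two-sided Wald p-values per coefficient."""
        se = self.robust_se if robust else self.model_se
        z = self.coefficients / se
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self, robust: bool = True) -> pd.DataFrame:
        se = self.robust_se if robust else self.model_se
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": se,
                "z": self.coefficients / se,
                "p": self.p_values(robust=robust),
            },
            index=self.design_column_names,
        )


@dataclass
class KMCurve:
    """Product-limit survival curve with Greenwood standard errors."""

    times: np.ndarray
    survival: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def at(self, t: float | np.ndarray) -> np.ndarray | float:
        """Step-function value S(t); 1 before the first distinct time."""
        idx = np.searchsorted(self.times, np.asarray(t), side="right")
        surv = np.concatenate([[1.0], self.survival])
        return surv[idx]


def _check_design(design: np.ndarray, names: list[str]) -> None:
    n, p = design.shape
    if n == 0:
        raise ValueError("empty design matrix")
    # QR rank check on the centred design (constant columns are unidentifiable
    # in a partial likelihood); near-zero diagonal of R names the columns.
    _, r = np.linalg.qr(design - design.mean(axis=0), mode="reduced")
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.max() > 0 else 1.0
    bad = diag < 1e-10 * scale
    if bad.any():
        cols = [names[j] for j in np.where(bad)[0]]
        raise ValueError(
            f"design matrix is rank deficient; collinear/constant column(s): {cols}"
        )


class _RiskSums:
    """Risk-set sums at event times for left-open (entry, exit] intervals.

    For any per-row weight vector w, the at-risk sum at time t is
    ``sum_{exit >= t} w - sum_{entry >= t} w`` because
    ``entry < t <= exit  <=>  (exit >= t) and not (entry >= t)``.
    Suffix cumulative sums over rows sorted by exit and by entry turn each
    evaluation into a binary search.
    """

    def __init__(self, entry: np.ndarray, exit_: np.ndarray, event_times: np.ndarray):
        self.exit_order = np.argsort(exit_, kind="mergesort")
        self.entry_order = np.argsort(entry, kind="mergesort")
        self.exit_sorted = exit_[self.exit_order]
        self.entry_sorted = entry[self.entry_order]
        # index of first row with exit >= t_j (resp. entry >= t_j)
        self.exit_idx = np.searchsorted(self.exit_sorted, event_times, side="left")
        self.entry_idx = np.searchsorted(self.entry_sorted, event_times, side="left")

    def __call__(self, w: np.ndarray) -> np.ndarray:
        """Risk-set sums of w at each event time; w may be (n,) or (n, ...)."""
        suffix_exit = np.zeros((len(w) + 1,) + w.shape[1:])
        suffix_exit[:-1] = np.cumsum(w[self.exit_order][::-1], axis=0)[::-1]
        suffix_entry = np.zeros_like(suffix_exit)
        suffix_entry[:-1] = np.cumsum(w[self.entry_order][::-1], axis=0)[::-1]
        return suffix_exit[self.exit_idx] - suffix_entry[self.entry_idx]


def cox_log_partial_likelihood(
    beta: np.ndarray,
    design: np.ndarray,
    entry: np.ndarray,
    exit_: np.ndarray,
    status: np.ndarray,
) -> float:
    """Breslow-ties log partial likelihood at ``beta`` (delayed entry aware)."""
    beta = np.asarray(beta, dtype=float)
    event_times, d = np.unique(exit_[status == 1], return_counts=True)
    sums = _RiskSums(entry, exit_, event_times)
    lp = design @ beta
    s0 = sums(np.exp(lp))
    return float(lp[status == 1].sum() - (d * np.log(s0)).sum())


def fit_partial_likelihood(
    design: np.ndarray,
    entry: np.ndarray,
    exit_: np.ndarray,
    status: np.ndarray,
    cluster_ids: np.ndarray | None = None,
    column_names: list[str] | None = None,
    tol_gradient: float = 1e-8,
    tol_loglik: float = 1e-9,
    max_iter: int = 100,
) -> CoxFit:
    """Fit a Cox model on counting-process rows by Newton-Raphson.

    Parameters
    ----------
    design : (n, p) numeric covariate matrix (already scaled/expanded).
    entry, exit_, status : per-row left-truncation time, end time, and event
        indicator; a row is at risk on the left-open interval (entry, exit].
    cluster_ids : grouping labels for the sandwich covariance; rows sharing a
        label (e.g. the same subject across landmarks) are treated as one
        correlated unit. ``None`` means one row per cluster.

    Notes
    -----
    Step-halving is applied whenever a Newton step decreases the likelihood.
    Convergence requires gradient norm < ``tol_gradient`` or a relative
    log-likelihood change < ``tol_loglik``.
    """
    design = np.asarray(design, dtype=float)
    entry = np.asarray(entry, dtype=float)
    exit_ = np.asarray(exit_, dtype=float)
    status = np.asarray(status, dtype=int)
    n, p = design.shape
    names = list(column_names) if column_names is not None else [f"x{j}" for j in range(p)]
    if np.any(entry >= exit_):
        raise ValueError("each row needs entry < exit")
    if status.sum() < 1:
        raise ValueError("no events: the partial likelihood is flat")
    _check_design(design, names)

    event_times, d = np.unique(exit_[status == 1], return_counts=True)
    sums = _RiskSums(entry, exit_, event_times)
    event_mask = status == 1
    sum_x_events = design[event_mask].sum(axis=0)

    def ll_grad_hess(beta):
        lp = np.clip(design @ beta, -500, 500)
        w = np.exp(lp)
        s0 = sums(w)  # (J,)
        s1 = sums(w[:, None] * design)  # (J, p)
        s2 = sums(w[:, None, None] * (design[:, :, None] * design[:, None, :]))
        mean = s1 / s0[:, None]
        ll = lp[event_mask].sum() - (d * np.log(s0)).sum()
        grad = sum_x_events - (d[:, None] * mean).sum(axis=0)
        hess = -(
            d[:, None, None]
            * (s2 / s0[:, None, None] - mean[:, :, None] * mean[:, None, :])
        ).sum(axis=0)
        return ll, grad, hess, s0, mean, w

    beta = np.zeros(p)
    ll, grad, hess, s0, mean, w = ll_grad_hess(beta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        step = np.linalg.solve(hess, -grad)
        new_beta = beta + step
        new = ll_grad_hess(new_beta)
        halvings = 0
        while new[0] < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new = ll_grad_hess(new_beta)
            halvings += 1
        rel_change = abs(new[0] - ll) / (abs(ll) + 1.0)
        beta = new_beta
        ll, grad, hess, s0, mean, w = new
        if np.linalg.norm(grad) < tol_gradient or rel_change < tol_loglik:
            break
    else:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations "
            f"(|grad| = {np.linalg.norm(grad):.3g}, loglik = {ll:.6g})"
        )

    information = -hess
    model_cov = np.linalg.inv(information)
    score = _score_residuals(
        design, entry, exit_, status, w, event_times, d, s0, mean
    )
    if cluster_ids is None:
        cluster_score = score
    else:
        cluster_ids = np.asarray(cluster_ids)
        frame = pd.DataFrame(score)
        frame["__c"] = cluster_ids
        cluster_score = frame.groupby("__c", sort=False).sum().to_numpy()
    meat = cluster_score.T @ cluster_score
    robust_cov = model_cov @ meat @ model_cov
    robust_cov = 0.5 * (robust_cov + robust_cov.T)

    return CoxFit(
        coefficients=beta,
        model_covariance=model_cov,
        robust_covariance=robust_cov,
        log_partial_likelihood=float(ll),
        n_iterations=n_iter,
        final_gradient_norm=float(np.linalg.norm(grad)),
        design_column_names=names,
    )


def _score_residuals(design, entry, exit_, status, w, event_times, d, s0, mean):
    """Per-row score residuals for the Breslow model (sandwich 'meat').

    U_i = d_i (x_i - xbar(t_i))
          - w_i [ x_i * sum_{t_j in (e_i, t_i]} dH0_j
                  - sum_{t_j in (e_i, t_i]} dH0_j xbar(t_j) ]
    """
    dh = d / s0
    cum_dh = np.concatenate([[0.0], np.cumsum(dh)])
    cum_dh_mean = np.concatenate(
        [np.zeros((1, design.shape[1])), np.cumsum(dh[:, None] * mean, axis=0)]
    )
    hi = np.searchsorted(event_times, exit_, side="right")
    lo = np.searchsorted(event_times, entry, side="right")
    a = cum_dh[hi] - cum_dh[lo]
    b = cum_dh_mean[hi] - cum_dh_mean[lo]
    resid = -w[:, None] * (design * a[:, None] - b)
    ev = status == 1
    # xbar at each event row's own event time
    j = np.searchsorted(event_times, exit_[ev])
    resid[ev] += design[ev] - mean[j]
    return resid


def breslow_baseline(
    entry: np.ndarray,
    exit_: np.ndarray,
    status: np.ndarray,
    linear_predictors: np.ndarray,
) -> BaselineHazard:
    """Breslow increments dH0(t_j) = d_j / sum_{at risk at t_j} exp(lp_i).

    With all linear predictors zero this reduces to the Nelson-Aalen
    increments d_j / n_j.
    """
    entry = np.asarray(entry, dtype=float)
    exit_ = np.asarray(exit_, dtype=float)
    status = np.asarray(status, dtype=int)
    event_times, d = np.unique(exit_[status == 1], return_counts=True)
    if len(event_times) == 0:
        return BaselineHazard(np.array([]), np.array([]))
    sums = _RiskSums(entry, exit_, event_times)
    s0 = sums(np.exp(np.asarray(linear_predictors, dtype=float)))
    return BaselineHazard(event_times=event_times, increments=d / s0)


def kaplan_meier(
    times: np.ndarray, status: np.ndarray, alpha: float = 0.05
) -> KMCurve:
    """Product-limit survival estimate with Greenwood SEs and log(-log) CIs.

    The point estimate comes from lifelines' Kaplan-Meier fitter; Greenwood
    variance and the exponential-Greenwood (log cumulative-hazard scale)
    confidence bounds are computed from its risk table, so the interval is
    guaranteed to stay inside [0, 1].
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    if len(times) == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=status)
    table = kmf.event_table.loc[kmf.event_table.index > 0]
    tgrid = table.index.to_numpy(dtype=float)
    d = table["observed"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    # exact product-limit from the risk table (exp-sum-log loses exactness)
    surv = np.cumprod(1.0 - d / n)
    # Greenwood: var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(n > d, d / (n * (n - d)), np.nan)
    gw = np.cumsum(np.nan_to_num(term, nan=0.0))
    se = surv * np.sqrt(gw)
    z = stats.norm.ppf(1 - alpha / 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        logH = np.log(-np.log(surv))
        sigma = np.sqrt(gw) / np.abs(np.log(surv))
    lo = np.where((surv > 0) & (surv < 1), surv ** np.exp(z * sigma), surv)
    hi = np.where((surv > 0) & (surv < 1), surv ** np.exp(-z * sigma), surv)
    return KMCurve(times=tgrid, survival=surv, se=se, ci_lower=lo, ci_upper=hi)
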