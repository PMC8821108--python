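"""Survival machinery: Kaplan-Meier, log-rank, Cox PH, and the
maximally-selected rank-statistic cutpoint.

The Cox model maximizes the Efron-tie-corrected partial likelihood by
Newton-Raphson with step-halving; standard errors come from the inverse
observed information.  The cutpoint search and the log-rank test share one
O-E / hypergeometric-variance kernel, so the squared standardized statistic
at a given split equals the two-group log-rank chi-square at that split.

Times are treated as unitless; every statistic here is invariant to a common
positive rescaling of the time axis, so cutpoints and hazard ratios are
consistent within any cohort whose times share one unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

__all__ = ["KMCurve", "CoxFit", "km_curve", "logrank_test", "logrank_zstat",
           "cox_fit", "best_cutpoint"]

_BETA_CAP = 20.0


def _check_surv(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValueError("no samples")
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return time, event.astype(int)


@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def at(self, t: float) -> float:
        """S(t); S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    @property
    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5 (nan if never reached)."""
        below = self.survival <= 0.5
        return float(self.event_times[below][0]) if below.any() else float("nan")


def km_curve(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i/n_i)."""
    time, event = _check_surv(time, event)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq = np.unique(t[e == 1])
    at_risk = np.array([(t >= u).sum() for u in uniq], dtype=int)
    deaths = np.array([((t == u) & (e == 1)).sum() for u in uniq], dtype=int)
    surv = np.cumprod(1.0 - deaths / at_risk) if uniq.size else np.array([])
    return KMCurve(uniq, surv, at_risk, deaths)


def _oev(time, event, groups):
    """O, E vectors and the hypergeometric covariance of O across groups."""
    k = groups.shape[1]
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for u in np.unique(time[event == 1]):
        at = time >= u
        n = at.sum()
        nj = groups[at].sum(axis=0).astype(float)
        dead = (time == u) & (event == 1)
        d = dead.sum()
        dj = groups[dead].sum(axis=0).astype(float)
        O += dj
        E += d * nj / n
        if n > 1:
            frac = nj / n
            V += d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
    return O, E, V


def logrank_test(time, event, group) -> tuple[float, int, float]:
    """K-sample log-rank test; returns (chi2, df, p)."""
    time, event = _check_surv(time, event)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size < 2:
        raise ValueError("need at least 2 groups")
    G = group[:, None] == levels[None, :]
    if (G.sum(axis=0) == 0).any():
        raise ValueError("empty group")
    O, E, V = _oev(time, event, G)
    d = (O - E)[:-1]
    Vr = V[:-1, :-1]
    stat = float(d @ np.linalg.pinv(Vr) @ d) if d.size else 0.0
    stat = max(stat, 0.0)
    df = int(levels.size - 1)
    return stat, df, float(chi2_dist.sf(stat, df))


def logrank_zstat(time, event, in_group) -> float:
    """Standardized two-group log-rank statistic (O1 - E1) / sqrt(V11)."""
    time, event = _check_surv(time, event)
    in_group = np.asarray(in_group, dtype=bool)
    G = np.column_stack([in_group, ~in_group])
    O, E, V = _oev(time, event, G)
    if V[0, 0] <= 0:
        return 0.0
    return float((O[0] - E[0]) / np.sqrt(V[0, 0]))


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model."""

    names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    log_partial_likelihood: float
    converged: bool
    n: int
    n_events: int
    n_iter: int
    separation: bool = False

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        lo = np.exp(self.beta - 1.96 * self.se)
        hi = np.exp(self.beta + 1.96 * self.se)
        return np.column_stack([lo, hi])

    @property
    def wald_p(self) -> np.ndarray:
        z = np.where(self.se > 0, self.beta / np.where(self.se == 0, 1, self.se), 0.0)
        return 2.0 * norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame({
            "covariate": self.names, "beta": self.beta, "se": self.se,
            "HR": self.hr, "ci95_low": ci[:, 0], "ci95_high": ci[:, 1],
            "wald_p": self.wald_p,
        })


def _efron_ll_grad_hess(beta, time, event, X):
    """Efron partial log-likelihood with gradient and Hessian."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    # iterate distinct times in decreasing order, growing the risk set
    order = np.argsort(-time, kind="stable")
    S0, S1, S2 = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    ts, ws, Xs, es = time[order], w[order], X[order], event[order]
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        for idx in range(i, j):
            S0 += ws[idx]
            S1 += ws[idx] * Xs[idx]
            S2 += ws[idx] * np.outer(Xs[idx], Xs[idx])
        dead = es[i:j] == 1
        d = int(dead.sum())
        if d:
            Xd = Xs[i:j][dead]
            wd = ws[i:j][dead]
            s0d = wd.sum()
            s1d = wd @ Xd
            s2d = (wd[:, None] * Xd).T @ Xd
            ll += float(np.log(ws[i:j][dead]).sum())
            grad += Xd.sum(axis=0)
            for l in range(d):
                f = l / d
                den = S0 - f * s0d
                nu1 = S1 - f * s1d
                nu2 = S2 - f * s2d
                ll -= np.log(den)
                grad -= nu1 / den
                hess -= nu2 / den - np.outer(nu1, nu1) / den**2
        i = j
    return ll, grad, hess


def cox_fit(time, event, covariates, names=None, tol: float = 1e-8,
            max_iter: int = 50) -> CoxFit:
    """Fit a Cox PH model by Newton-Raphson on the Efron partial likelihood.

    ``covariates`` is an (n, p) array or DataFrame.  Convergence when
    max |score| < tol; step-halving keeps the partial likelihood
    non-decreasing.  A monotone (separated) likelihood is detected when a
    coefficient runs past +/-20; the coefficient is capped there with a
    warning and the fit flagged.
    """
    time, event = _check_surv(time, event)
    if isinstance(covariates, pd.DataFrame):
        names = names or tuple(map(str, covariates.columns))
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = tuple(names) if names else tuple(f"x{i}" for i in range(X.shape[1]))
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > number of covariates ({n} <= {p})")
    const = X.std(axis=0) == 0
    if const.any():
        raise ValueError(f"constant covariate(s): {[names[i] for i in np.flatnonzero(const)]}")
    if event.sum() == 0:
        raise ValueError("no events observed")
    # center for numerical stability (does not change beta)
    mu = X.mean(axis=0)
    Xc = X - mu

    beta = np.zeros(p)
    ll, grad, hess = _efron_ll_grad_hess(beta, time, event, Xc)
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        new_beta = beta + step
        new_ll, new_grad, new_hess = _efron_ll_grad_hess(
            new_beta, time, event, Xc)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _efron_ll_grad_hess(
                new_beta, time, event, Xc)
            halvings += 1
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.max(np.abs(beta)) > _BETA_CAP:
            separation = True
            warnings.warn(
                "monotone partial likelihood (complete separation?); "
                f"coefficients capped at +/-{_BETA_CAP}")
            beta = np.clip(beta, -_BETA_CAP, _BETA_CAP)
            ll, grad, hess = _efron_ll_grad_hess(beta, time, event, Xc)
            break
    else:
        it = max_iter
    if np.max(np.abs(grad)) < tol and not separation:
        converged = True
    if not converged and not separation:
        warnings.warn("Cox fit did not converge; inspect diagnostics")
    info = -hess
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return CoxFit(names=names, beta=beta, se=se,
                  log_partial_likelihood=float(ll),
                  converged=converged, n=n, n_events=int(event.sum()),
                  n_iter=it, separation=separation)


def best_cutpoint(score, time, event, minprop: float = 0.1
                  ) -> tuple[float, float]:
    """Maximally selected rank statistic cutpoint of a continuous score.

    Every distinct score value whose split (score <= c vs > c) leaves at
    least ceil(minprop * n) subjects on each side is tested with the
    standardized two-group log-rank statistic; the cutpoint maximizing the
    absolute statistic is returned together with that maximum (ties broken
    toward the smallest cutpoint).  Group membership is invariant under
    strictly increasing transforms of the score.
    """
    if not 0 < minprop < 0.5:
        raise ValueError("minprop must be in (0, 0.5)")
    score = np.asarray(score, dtype=float)
    time, event = _check_surv(time, event)
    n = score.size
    min_n = int(np.ceil(minprop * n))
    candidates = np.unique(score)
    best_c, best_z = None, 0.0
    for c in candidates:
        low = score <= c
        n_low = int(low.sum())
        if n_low < min_n or n - n_low < min_n:
            continue
        z = logrank_zstat(time, event, low)
        if best_c is None or abs(z) > abs(best_z) + 1e-12:
            best_c, best_z = float(c), z
    if best_c is None:
        raise ValueError("no admissible cutpoint satisfies minprop")
    return best_c, float(abs(best_z))
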