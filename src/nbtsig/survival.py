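"""Survival analysis: Kaplan-Meier, log-rank, and Cox proportional hazards.

The Cox model maximizes the Efron-tie-corrected log partial likelihood by
Newton-Raphson with step-halving (Breslow ties available; with Breslow ties
the score test at beta = 0 for a binary covariate reproduces the log-rank
chi-square exactly).  Standard errors come from the inverse observed
information; 95% confidence intervals are Wald intervals on beta.

Conventions: at tied times, events precede censorings (a subject censored at
t is still at risk for the event at t); times must be positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, NumericalError

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "km_estimate",
    "survival_at",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "screen_then_multivariate",
]

log = logging.getLogger(__name__)


def _check_times(time: np.ndarray) -> None:
    if np.any(time <= 0) or np.any(~np.isfinite(time)):
        raise DataError("survival times must be positive and finite")


@dataclass
class KMCurve:
    """Product-limit estimate tabulated at distinct event times."""

    table: pd.DataFrame  # time, n_risk, n_event, n_censor, survival, std_err

    def survival_at(self, t: float) -> float:
        return survival_at(self, t)


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


@dataclass
class CoxFit:
    summary: pd.DataFrame       # beta, se, hr, ci_low, ci_high, p per covariate
    log_likelihood: float
    converged: bool
    n_iter: int
    ties: str
    separation_suspected: bool = False
    n: int = 0
    n_events: int = 0

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator with Greenwood standard errors."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise DataError("empty survival data")
    _check_times(time)

    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    n = time.size

    rows = []
    surv = 1.0
    green = 0.0
    i = 0
    while i < n:
        t = time[i]
        j = i
        while j < n and time[j] == t:
            j += 1
        d = int(event[i:j].sum())
        c = (j - i) - d
        at_risk = n - i
        if d > 0:
            surv *= 1.0 - d / at_risk
            if at_risk > d:
                green += d / (at_risk * (at_risk - d))
            rows.append(
                dict(time=t, n_risk=at_risk, n_event=d, n_censor=c,
                     survival=surv, std_err=surv * np.sqrt(green))
            )
        i = j
    table = pd.DataFrame(rows, columns=["time", "n_risk", "n_event", "n_censor",
                                        "survival", "std_err"])
    return KMCurve(table=table)


def survival_at(km: KMCurve, t: float) -> float:
    """S-hat(t): the step function evaluated at t (1 before the first event)."""
    tab = km.table
    prior = tab[tab["time"] <= t]
    return 1.0 if prior.empty else float(prior["survival"].iloc[-1])


def logrank_test(times: list, events: list) -> LogRankResult:
    """K-sample log-rank test.

    ``times`` and ``events`` are per-group sequences.  The chi-square is the
    quadratic form of observed-minus-expected event counts with the
    hypergeometric covariance summed over distinct event times, using the
    first K-1 groups; df = K - 1.
    """
    k = len(times)
    if k < 2:
        raise DataError("log-rank needs at least two groups")
    t_all, e_all, g_all = [], [], []
    for g, (t, e) in enumerate(zip(times, events)):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise DataError(f"group {g} is empty")
        _check_times(t)
        t_all.append(t); e_all.append(e); g_all.append(np.full(t.size, g))
    t = np.concatenate(t_all)
    e = np.concatenate(e_all)
    g = np.concatenate(g_all)
    if e.sum() == 0:
        raise DataError("no events in any group")

    event_times = np.unique(t[e == 1])
    obs = np.zeros(k)
    exp_ = np.zeros(k)
    cov = np.zeros((k, k))
    for tt in event_times:
        at_risk = t >= tt
        n_j = at_risk.sum()
        d_j = int(((t == tt) & (e == 1)).sum())
        n_gj = np.array([(at_risk & (g == gr)).sum() for gr in range(k)], dtype=float)
        d_gj = np.array([((t == tt) & (e == 1) & (g == gr)).sum() for gr in range(k)],
                        dtype=float)
        obs += d_gj
        exp_ += d_j * n_gj / n_j
        if n_j > 1:
            frac = n_gj / n_j
            v = d_j * (n_j - d_j) / (n_j - 1)
            cov += v * (np.diag(frac) - np.outer(frac, frac))
    diff = (obs - exp_)[: k - 1]
    vmat = cov[: k - 1, : k - 1]
    try:
        chi2 = float(diff @ np.linalg.solve(vmat, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(vmat) @ diff)
    chi2 = max(chi2, 0.0)
    df = k - 1
    return LogRankResult(chi_square=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df)))


def _cox_ll_grad_info(beta, x, time, event, ties):
    """Log partial likelihood, score and information (Efron or Breslow)."""
    n, p = x.shape
    eta = x @ beta
    w = np.exp(eta)
    order = np.argsort(-time, kind="mergesort")  # descending time
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    # cumulative risk-set sums, built walking times downward
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    m = order.size
    while i < m:
        t = time[order[i]]
        j = i
        while j < m and time[order[j]] == t:
            idx = order[j]
            s0 += w[idx]
            s1 += w[idx] * x[idx]
            s2 += w[idx] * np.outer(x[idx], x[idx])
            j += 1
        deaths = [order[r] for r in range(i, j) if event[order[r]] == 1]
        d = len(deaths)
        if d:
            wd = w[deaths]
            xd = x[deaths]
            d0 = wd.sum()
            d1 = (wd[:, None] * xd).sum(axis=0)
            d2 = np.einsum("i,ij,ik->jk", wd, xd, xd)
            ll += eta[deaths].sum()
            for l in range(d):
                frac = (l / d) if ties == "efron" else 0.0
                z0 = s0 - frac * d0
                z1 = s1 - frac * d1
                z2 = s2 - frac * d2
                ll -= np.log(z0)
                grad_term = z1 / z0
                grad -= grad_term
                info += z2 / z0 - np.outer(grad_term, grad_term)
        grad += x[deaths].sum(axis=0) if d else 0.0
        i = j
    return ll, grad, info


def cox_fit(
    x: pd.DataFrame,
    time,
    event,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson with step-halving.

    ``x`` holds numeric covariate columns, one row per subject.  Convergence
    when the max absolute score or the log-likelihood change drops below
    ``tol``.  A constant covariate raises; divergent coefficients (monotone
    likelihood / complete separation) are flagged, not silently reported.
    """
    if ties not in ("efron", "breslow"):
        raise DataError(f"unknown ties method {ties!r}")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _check_times(time)
    if event.sum() < 1:
        raise DataError("Cox fit needs at least one event")
    xm = x.to_numpy(dtype=float)
    for name in x.columns:
        if np.ptp(x[name].to_numpy(dtype=float)) == 0:
            raise DataError(f"covariate {name!r} is constant (non-identifiable)")

    p = xm.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _cox_ll_grad_info(beta, xm, time, event, ties)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise NumericalError("singular information matrix in Cox fit") from exc
        # step-halving if the likelihood does not improve
        new_beta = beta + step
        new_ll, new_grad, new_info = _cox_ll_grad_info(new_beta, xm, time, event, ties)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            halvings += 1
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox_ll_grad_info(new_beta, xm, time, event, ties)
        delta_ll = new_ll - ll
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if np.max(np.abs(grad)) < tol or abs(delta_ll) < tol:
            converged = True
            break

    separation = bool(np.max(np.abs(beta)) > 10)
    if separation:
        log.warning("Cox fit: |beta| > 10, monotone likelihood suspected")
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("information matrix not invertible at optimum") from exc
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        zval = beta / se
        pvals = 2.0 * stats.norm.sf(np.abs(zval))
        summary = pd.DataFrame(
            {
                "beta": beta,
                "se": se,
                "hr": np.exp(beta),
                "ci_low": np.exp(beta - 1.959963984540054 * se),
                "ci_high": np.exp(beta + 1.959963984540054 * se),
                "p": pvals,
            },
            index=pd.Index(x.columns, name="covariate"),
        )
    return CoxFit(
        summary=summary,
        log_likelihood=float(ll),
        converged=converged,
        n_iter=n_iter,
        ties=ties,
        separation_suspected=separation,
        n=int(time.size),
        n_events=int(event.sum()),
    )


def cox_score_test(x: pd.DataFrame, time, event, ties: str = "breslow"):
    """Score (Rao) test of beta = 0: U(0)' I(0)^-1 U(0) ~ chi2(p).

    With Breslow ties and a single binary covariate this equals the two-group
    log-rank chi-square.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _check_times(time)
    xm = x.to_numpy(dtype=float)
    _, grad, info = _cox_ll_grad_info(np.zeros(xm.shape[1]), xm, time, event, ties)
    chi2 = float(grad @ np.linalg.solve(info, grad))
    df = xm.shape[1]
    return chi2, df, float(stats.chi2.sf(chi2, df))


def screen_then_multivariate(
    data: pd.DataFrame,
    time_col: str,
    event_col: str,
    covariates: list[str],
    screen_p: float = 0.1,
    ties: str = "efron",
) -> tuple[dict[str, CoxFit], CoxFit | None]:
    """Univariate screening (Wald p < screen_p) into one multivariate model.

    Each candidate covariate gets a univariate Cox fit; those with Wald
    p below the screening threshold enter a joint model.  Returns
    (univariate fits by covariate, multivariate fit or None when no
    covariate qualifies).
    """
    if len(covariates) < 2:
        raise DataError("screening needs at least two candidate covariates")
    uni: dict[str, CoxFit] = {}
    qualifying = []
    for cov in covariates:
        fit = cox_fit(data[[cov]], data[time_col], data[event_col], ties=ties)
        uni[cov] = fit
        if float(fit.summary.loc[cov, "p"]) < screen_p:
            qualifying.append(cov)
    if not qualifying:
        log.warning("no covariate passed the univariate screen (p < %g)", screen_p)
        return uni, None
    multi = cox_fit(data[qualifying], data[time_col], data[event_col], ties=ties)
    return uni, multi
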