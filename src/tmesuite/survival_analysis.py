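"""Survival statistics: Kaplan-Meier curves, log-rank tests, univariate Cox
proportional-hazards fits, and maximally selected log-rank cutpoints.

Kaplan-Meier estimation and the log-rank test are delegated to lifelines.
The univariate Cox fit is a direct Newton maximization of the Breslow
partial likelihood: Breslow tie handling keeps the likelihood in closed form
so independent oracles (and reference implementations on tie-free data)
agree to machine precision, and a one-parameter Newton iteration is robust
and gives the Wald standard error from the observed information for free.

Tie convention throughout: at equal times, events precede censorings (the
risk set at an event time includes samples censored at that same time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .io_core import SurvivalTable, ValidationError

logger = logging.getLogger("tmesuite")

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "optimal_cutpoint",
    "breslow_loglik",
]


@dataclass
class KMCurve:
    """Product-limit estimate for one group: values at observed event times."""

    group: object
    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValidationError("survival curve must be non-increasing")


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


@dataclass
class CoxFit:
    """Univariate proportional-hazards fit (per unit of the covariate)."""

    log_hr: float
    se: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool
    n_iter: int


def km_estimate(surv: SurvivalTable, groups: dict[str, object]) -> dict[object, KMCurve]:
    """Kaplan-Meier curve per group.

    ``groups`` maps sample id -> group label; every sample in ``surv`` must
    be labeled and every group must be non-empty.
    """
    labels = np.array([groups[s] for s in surv.sample_ids], dtype=object)
    curves: dict[object, KMCurve] = {}
    for g in dict.fromkeys(labels):
        mask = labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time[mask], surv.event[mask])
        table = kmf.event_table
        ev = table[table["observed"] > 0]
        if len(ev) == 0:
            logger.info("group %r has no events; survival curve is flat at 1", g)
            curves[g] = KMCurve(g, np.array([]), np.array([]), np.array([]))
            continue
        times = ev.index.to_numpy(dtype=float)
        s = kmf.survival_function_at_times(times).to_numpy()
        curves[g] = KMCurve(g, times, s, ev["at_risk"].to_numpy())
    return curves


def logrank_test(surv: SurvivalTable, groups: dict[str, object]) -> LogRankResult:
    """K-sample log-rank test over pooled event times."""
    labels = np.array([groups[s] for s in surv.sample_ids], dtype=object)
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise ValidationError("log-rank test needs at least 2 groups")
    if surv.event.sum() < 1:
        raise ValidationError("log-rank test needs at least 1 event")
    res = multivariate_logrank_test(surv.time, labels, surv.event)
    chi = float(res.test_statistic)
    df = len(uniq) - 1
    return LogRankResult(chi, df, float(stats.chi2.sf(chi, df)))


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties)
# ---------------------------------------------------------------------------

def breslow_loglik(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                   beta: np.ndarray) -> float:
    """Breslow log partial likelihood for covariates ``x`` (n x p) at ``beta``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != len(time):
        x = x.T
    eta = x @ np.atleast_1d(beta)
    order = np.argsort(-time, kind="stable")
    eta_o, t_o, e_o = eta[order], time[order], event[order]
    # cumulative sum over risk sets (descending time)
    csum = np.cumsum(np.exp(eta_o))
    # for tied times the risk set extends to the last index sharing that time
    ll = 0.0
    i = 0
    n = len(t_o)
    while i < n:
        j = i
        while j + 1 < n and t_o[j + 1] == t_o[i]:
            j += 1
        risk = csum[j]
        for idx in range(i, j + 1):
            if e_o[idx] == 1:
                ll += eta_o[idx] - np.log(risk)
        i = j + 1
    return float(ll)


def _cox_derivatives(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                     beta: float) -> tuple[float, float, float]:
    """(loglik, gradient, negative hessian) for a single covariate, Breslow ties."""
    order = np.argsort(-time, kind="stable")
    x_o, t_o, e_o = x[order], time[order], event[order]
    w = np.exp(beta * x_o)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * x_o)
    s2 = np.cumsum(w * x_o * x_o)
    ll = grad = info = 0.0
    i, n = 0, len(t_o)
    while i < n:
        j = i
        while j + 1 < n and t_o[j + 1] == t_o[i]:
            j += 1
        d = int(e_o[i : j + 1].sum())
        if d:
            xe = float(x_o[i : j + 1][e_o[i : j + 1] == 1].sum())
            r0, r1, r2 = s0[j], s1[j], s2[j]
            ll += beta * xe - d * np.log(r0)
            grad += xe - d * r1 / r0
            info += d * (r2 / r0 - (r1 / r0) ** 2)
        i = j + 1
    return ll, grad, info


def cox_univariate(x: np.ndarray, surv: SurvivalTable, max_iter: int = 100,
                   tol: float = 1e-9) -> CoxFit:
    """Newton maximization of the univariate Breslow partial likelihood.

    Returns the per-unit log hazard ratio with Wald 95% CI and p-value.
    A zero-variance covariate (or non-convergence) yields the null fit
    log HR = 0 with ``converged=False``.
    """
    x = np.asarray(x, dtype=float)
    if len(x) != len(surv):
        raise ValidationError("covariate length does not match survival table")
    if surv.event.sum() < 2:
        raise ValidationError("need at least 2 events for a Cox fit")
    if np.std(x) == 0:
        logger.warning("zero-variance covariate: returning null Cox fit")
        return CoxFit(0.0, np.inf, 1.0, 0.0, np.inf, 1.0, False, 0)

    beta = 0.0
    converged = False
    it = 0
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        ll, grad, info = _cox_derivatives(x, surv.time, surv.event, beta)
        if info <= 0:
            break
        step = grad / info
        # step-halving if the likelihood would decrease
        for _ in range(20):
            ll_new, _, _ = _cox_derivatives(x, surv.time, surv.event, beta + step)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta += step
        if abs(step) < tol or abs(ll_new - ll_old) < tol * (abs(ll_old) + 1):
            converged = True
            break
        ll_old = ll_new
    if not converged:
        logger.warning("Cox Newton iteration did not converge; returning null fit")
        return CoxFit(0.0, np.inf, 1.0, 0.0, np.inf, 1.0, False, it)

    _, _, info = _cox_derivatives(x, surv.time, surv.event, beta)
    se = float(1.0 / np.sqrt(info))
    z = beta / se
    ci = 1.959963984540054 * se
    return CoxFit(
        log_hr=float(beta),
        se=se,
        hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - ci)),
        ci_high=float(np.exp(beta + ci)),
        p_value=float(2 * stats.norm.sf(abs(z))),
        converged=True,
        n_iter=it,
    )


def optimal_cutpoint(
    x: np.ndarray,
    surv: SurvivalTable,
    quantile_band: tuple[float, float] = (0.1, 0.9),
) -> tuple[float, dict[str, str], LogRankResult]:
    """Maximally selected log-rank split of a continuous marker.

    Every distinct value of ``x`` inside the quantile band is tried as a
    threshold (high = strictly above); the cutpoint maximizing the two-group
    log-rank statistic is returned (ties -> lower cutpoint).  The reported
    p-value is the naive log-rank p at the chosen cut and is NOT adjusted
    for the selection, which makes it anti-conservative.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 20:
        raise ValidationError("cutpoint search needs >= 20 samples")
    lo, hi = np.quantile(x, quantile_band)
    candidates = np.unique(x[(x >= lo) & (x <= hi)])
    # a threshold at the maximum puts no sample in the high group
    candidates = candidates[candidates < x.max()]
    if len(candidates) < 1 or len(np.unique(x[(x >= lo) & (x <= hi)])) < 2:
        raise ValidationError("fewer than 2 distinct values in the quantile band")
    best = None
    for cut in candidates:
        groups = {s: ("high" if xi > cut else "low") for s, xi in zip(surv.sample_ids, x)}
        res = logrank_test(surv, groups)
        if best is None or res.chi_square > best[1].chi_square + 1e-12:
            best = (float(cut), res, groups)
    cut, res, groups = best
    logger.warning(
        "optimal_cutpoint p-value (%.3g) is not adjusted for cutpoint selection", res.p_value
    )
    return cut, groups, res
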