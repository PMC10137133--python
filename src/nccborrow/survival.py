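"""Delayed-entry survival estimation built from first principles.

Risk sets follow the left-truncation convention {j : exit_j >= t > entry_j}
(entry strict, exit inclusive).  On top of that convention this module
provides the product-limit (Kaplan–Meier) estimator with Greenwood
variance, the Cox partial likelihood for a single binary covariate with
Newton–Raphson maximization and Wald inference, the two-sample log-rank
test, and deliberately naive brute-force oracles used to cross-check the
fast paths.

The fast paths exploit the binary covariate: every risk-set sum over
exp(beta*x) reduces to n0(t) + n1(t)*exp(beta), with the per-group at-risk
counts n_g(t) = #{exit >= t} − #{entry >= t} obtained from sorted arrays.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Z95",
    "DegenerateCovariateError",
    "KMEstimate",
    "CoxFit",
    "LogRankResult",
    "WaldSummary",
    "risk_set",
    "km_fit",
    "cox_loglik",
    "cox_fit",
    "cox_score_test",
    "wald_summary",
    "logrank_test",
    "brute_force_loglik",
    "brute_force_fit",
]

Z95 = float(stats.norm.ppf(0.975))  # 1.959964


class DegenerateCovariateError(ValueError):
    """The group covariate carries no information (constant, or no overlap)."""


def _as_arrays(records) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Accepts a sequence of AnalysisRecord-likes or a DataFrame."""
    if hasattr(records, "columns"):
        entry = records["entry"].to_numpy(dtype=float)
        exit_ = records["exit"].to_numpy(dtype=float)
        event = records["event"].to_numpy().astype(bool)
        x = records["group"].to_numpy(dtype=float)
    else:
        entry = np.array([r.entry for r in records], dtype=float)
        exit_ = np.array([r.exit for r in records], dtype=float)
        event = np.array([r.event for r in records], dtype=bool)
        x = np.array([r.group for r in records], dtype=float)
    if np.any(exit_ <= entry):
        raise ValueError("every record needs exit > entry")
    return entry, exit_, event, x


def _n_at_risk(entry: np.ndarray, exit_: np.ndarray, times: np.ndarray) -> np.ndarray:
    """#{j : exit_j >= t > entry_j} for each t, via sorted searchsorted."""
    es = np.sort(entry)
    ys = np.sort(exit_)
    return np.searchsorted(es, times, side="left") - np.searchsorted(ys, times, side="left")


def risk_set(records, t: float) -> set[int]:
    """Indices at risk at analysis time ``t`` (literal definition)."""
    if t <= 0:
        raise ValueError("risk sets are defined for t > 0")
    entry, exit_, _, _ = _as_arrays(records)
    return {j for j in range(len(exit_)) if exit_[j] >= t and t > entry[j]}


# ---------------------------------------------------------------------------
# Kaplan–Meier

@dataclass
class KMEstimate:
    """Product-limit estimate over the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    variance: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def survival_at(self, t) -> np.ndarray | float:
        """Step-function lookup; S = 1 before the first event time."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate(([1.0], self.survival))
        out = s[idx]
        return float(out) if out.ndim == 0 else out


def km_fit(records, ci_method: str = "loglog", alpha: float = 0.05) -> KMEstimate:
    """Delayed-entry Kaplan–Meier with Greenwood variance.

    Pointwise CIs on the log(−log) scale by default; ``ci_method='linear'``
    gives plain Greenwood intervals clipped to [0, 1].
    """
    entry, exit_, event, _ = _as_arrays(records)
    if len(exit_) == 0:
        raise ValueError("need at least one record")
    if not event.any():
        empty = np.array([])
        return KMEstimate(empty, empty, empty, empty, empty, empty, empty)
    times, d = np.unique(exit_[event], return_counts=True)
    n = _n_at_risk(entry, exit_, times)
    surv = np.cumprod(1.0 - d / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), np.inf)
        cum = np.cumsum(terms)
        var = np.where(surv > 0, surv**2 * cum, 0.0)
        z = float(stats.norm.ppf(1 - alpha / 2))
        if ci_method == "loglog":
            ok = (surv > 0) & (surv < 1)
            se_theta = np.sqrt(cum, where=np.isfinite(cum), out=np.full_like(cum, np.inf))
            se_theta = np.where(ok, se_theta / np.abs(np.log(np.where(ok, surv, 0.5))), np.inf)
            lo = np.where(ok, surv ** np.exp(z * se_theta), 0.0)
            hi = np.where(ok, surv ** np.exp(-z * se_theta), np.where(surv >= 1, 1.0, 0.0))
        elif ci_method == "linear":
            half = z * np.sqrt(var)
            lo = np.clip(surv - half, 0.0, 1.0)
            hi = np.clip(surv + half, 0.0, 1.0)
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
    return KMEstimate(times, surv, n, d, var, lo, hi)


# ---------------------------------------------------------------------------
# Cox partial likelihood (single binary covariate)

class WaldSummary(NamedTuple):
    hr: float
    ci: tuple[float, float]
    p: float


def _safe_exp(v: float) -> float:
    try:
        return math.exp(v)
    except OverflowError:
        return math.inf


def wald_summary(beta: float, se: float) -> WaldSummary:
    """Hazard ratio, 95% Wald CI and two-sided p from (beta, se)."""
    if se <= 0:
        raise ValueError("se must be positive")
    hr = _safe_exp(beta)
    ci = (_safe_exp(beta - Z95 * se), _safe_exp(beta + Z95 * se))
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return WaldSummary(hr, ci, p)


@dataclass
class CoxFit:
    beta: float
    se: float
    hr: float
    ci: tuple[float, float]
    p: float
    loglik: float
    iterations: int
    converged: bool
    n: int
    n_events: int


class _EventTable(NamedTuple):
    times: np.ndarray   # distinct event times
    d: np.ndarray       # events per time
    e1: np.ndarray      # group-1 events per time
    n0: np.ndarray      # group-0 at risk
    n1: np.ndarray      # group-1 at risk


def _event_table(entry, exit_, event, x) -> _EventTable:
    times, inv, d = np.unique(exit_[event], return_inverse=True, return_counts=True)
    e1 = np.bincount(inv, weights=x[event], minlength=len(times))
    g1 = x == 1
    n1 = _n_at_risk(entry[g1], exit_[g1], times)
    n0 = _n_at_risk(entry[~g1], exit_[~g1], times)
    return _EventTable(times, d, e1, n0, n1)


def _partial_lik(tab: _EventTable, beta: float, ties: str):
    """(loglik, score, information) at ``beta``.

    Efron handles tied event times by subtracting the fraction l/d of the
    tied subjects' risk contribution from the denominator of the l-th tied
    term; with f = 0 this reduces to Breslow.
    """
    u = math.exp(beta)
    d = tab.d
    e1 = tab.e1
    e0 = d - e1
    total = int(d.sum())
    idx = np.repeat(np.arange(len(d)), d)
    if ties == "efron":
        starts = np.cumsum(d) - d
        l = np.arange(total) - np.repeat(starts, d)
        f = l / np.repeat(d, d)
    elif ties == "breslow":
        f = np.zeros(total)
    else:
        raise ValueError(f"unknown tie method {ties!r}")
    s0 = tab.n0 + tab.n1 * u
    s0_tied = e0 + e1 * u
    denom = s0[idx] - f * s0_tied[idx]
    numer = u * (tab.n1[idx] - f * e1[idx])
    loglik = beta * float(e1.sum()) - float(np.log(denom).sum())
    r = numer / denom
    score = float(e1.sum() - r.sum())
    info = float((r - r * r).sum())
    return loglik, score, info


def cox_loglik(records, beta: float, ties: str = "efron") -> float:
    """Partial log-likelihood at ``beta`` with delayed-entry risk sets."""
    entry, exit_, event, x = _as_arrays(records)
    if not event.any():
        return 0.0
    tab = _event_table(entry, exit_, event, x)
    return _partial_lik(tab, beta, ties)[0]


def cox_fit(
    records,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 25,
    divergence_bound: float = 15.0,
) -> CoxFit:
    """Maximize the partial likelihood by Newton–Raphson from beta = 0.

    Convergence on |score| < ``tol`` with step-halving on any likelihood
    decrease; |beta| exceeding ``divergence_bound`` is flagged as a
    monotone likelihood (converged=False) rather than an error.
    """
    entry, exit_, event, x = _as_arrays(records)
    if len(np.unique(x)) < 2:
        raise DegenerateCovariateError("group covariate is constant")
    if not set(np.unique(x)) <= {0.0, 1.0}:
        raise ValueError("group covariate must be coded 0/1")
    if not event.any():
        raise DegenerateCovariateError("no events observed")
    tab = _event_table(entry, exit_, event, x)
    beta = 0.0
    ll, score, info = _partial_lik(tab, beta, ties)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        if info <= 0:
            raise DegenerateCovariateError("groups never share a risk set at an event time")
        if abs(score) < tol:
            converged = True
            break
        step = score / info
        new_beta = beta + step
        new_ll, new_score, new_info = _partial_lik(tab, new_beta, ties)
        halvings = 0
        # tolerate rounding-level decreases, else Newton stalls at the optimum
        while new_ll < ll - 1e-10 * (1.0 + abs(ll)) and halvings < 30:
            step *= 0.5
            halvings += 1
            new_beta = beta + step
            new_ll, new_score, new_info = _partial_lik(tab, new_beta, ties)
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if abs(beta) > divergence_bound:
            warnings.warn(
                "partial likelihood appears monotone (|beta| > "
                f"{divergence_bound:g}); estimate unreliable",
                stacklevel=2,
            )
            break
    se = 1.0 / math.sqrt(info) if info > 0 else math.inf
    hr, ci, p = wald_summary(beta, se) if math.isfinite(se) else (_safe_exp(beta), (0.0, math.inf), 1.0)
    return CoxFit(
        beta=beta,
        se=se,
        hr=hr,
        ci=ci,
        p=p,
        loglik=ll,
        iterations=iterations,
        converged=converged,
        n=len(exit_),
        n_events=int(event.sum()),
    )


def cox_score_test(records, ties: str = "breslow") -> tuple[float, float]:
    """Score (Rao) chi-squared test of beta = 0; equals the log-rank test
    on tie-free data."""
    entry, exit_, event, x = _as_arrays(records)
    tab = _event_table(entry, exit_, event, x)
    _, score, info = _partial_lik(tab, 0.0, ties)
    if info <= 0:
        raise DegenerateCovariateError("no between-group information at beta = 0")
    statistic = score**2 / info
    return float(statistic), float(stats.chi2.sf(statistic, 1))


# ---------------------------------------------------------------------------
# Log-rank

@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float
    observed: dict
    expected: dict
    valid: bool = True


def logrank_test(records, groups: Sequence | None = None) -> LogRankResult:
    """Two-sample log-rank test with delayed-entry risk sets.

    ``groups`` labels each record (defaults to the 0/1 group covariate).
    Observed-minus-expected with hypergeometric variance at each distinct
    event time; with no events the statistic is undefined and p = 1.
    """
    entry, exit_, event, x = _as_arrays(records)
    labels = np.asarray(list(groups)) if groups is not None else x
    if len(labels) != len(exit_):
        raise ValueError("one group label per record required")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {len(uniq)}")
    g1 = labels == uniq[1]
    if not event.any():
        zeros = {uniq[0]: 0.0, uniq[1]: 0.0}
        return LogRankResult(0.0, 1, 1.0, zeros, zeros, valid=False)
    tab = _event_table(entry, exit_, event, g1.astype(float))
    n = tab.n0 + tab.n1
    d = tab.d
    exp1 = d * tab.n1 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(
            n > 1,
            d * (tab.n1 / n) * (tab.n0 / n) * (n - d) / np.maximum(n - 1, 1),
            0.0,
        )
    o1 = float(tab.e1.sum())
    o0 = float(d.sum() - o1)
    v = float(var.sum())
    observed = {uniq[0]: o0, uniq[1]: o1}
    expected = {uniq[0]: float(d.sum() - exp1.sum()), uniq[1]: float(exp1.sum())}
    if v <= 0:
        return LogRankResult(0.0, 1, 1.0, observed, expected, valid=False)
    statistic = (o1 - expected[uniq[1]]) ** 2 / v
    return LogRankResult(float(statistic), 1, float(stats.chi2.sf(statistic, 1)), observed, expected)


# ---------------------------------------------------------------------------
# Brute-force oracles (literal enumeration; small instances only)

def brute_force_loglik(records, beta: float, ties: str = "efron") -> float:
    """Partial log-likelihood by literal risk-set enumeration."""
    entry, exit_, event, x = _as_arrays(records)
    idx_all = range(len(exit_))
    ll = 0.0
    for t in sorted({exit_[j] for j in idx_all if event[j]}):
        tied = [j for j in idx_all if event[j] and exit_[j] == t]
        at_risk = [j for j in idx_all if exit_[j] >= t and t > entry[j]]
        s_risk = sum(math.exp(beta * x[j]) for j in at_risk)
        s_tied = sum(math.exp(beta * x[j]) for j in tied)
        d = len(tied)
        ll += beta * sum(x[j] for j in tied)
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            ll -= math.log(s_risk - frac * s_tied)
    return ll


def brute_force_fit(records, ties: str = "efron", bound: float = 15.0) -> float:
    """Maximize the brute-force partial likelihood by bounded 1-D search."""
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda b: -brute_force_loglik(records, b, ties),
        bounds=(-bound, bound),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)
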