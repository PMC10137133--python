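"""Strategy comparison and Monte Carlo operating characteristics.

One simulated dataset yields a comparison table (one row per analysis
strategy); repeated simulation yields bias, empirical SD, mean model SE,
CI coverage and rejection rate per strategy, which is how the efficiency
gain from borrowing NCC concurrent observation time is quantified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import SubjectRecord, TrialDesign, simulate_trial
from .survival import (
    DegenerateCovariateError,
    LogRankResult,
    cox_fit,
    logrank_test,
)
from .truncation import Origin, Strategy, build_analysis_set

__all__ = [
    "UnsupportedDesignError",
    "StrategyRow",
    "MCSummary",
    "true_hazard_ratio",
    "run_strategy",
    "comparison_table",
    "table_to_frame",
    "exchangeability_check",
    "monte_carlo",
    "mc_to_frame",
]

ALPHA = 0.05


class UnsupportedDesignError(ValueError):
    """The design's post-changepoint hazards are not constant/shared."""


@dataclass
class StrategyRow:
    """One line of the strategy-comparison table."""

    strategy: Strategy
    n_records: int
    n_events: int
    n_truncated_out: int
    true_hr: float
    beta: float
    hr: float
    se: float
    ci: tuple[float, float]
    p: float
    converged: bool


@dataclass
class MCSummary:
    """Per-strategy operating characteristics over replicates.

    ``empirical_sd`` is None when fewer than two converged replicates are
    available; non-converged fits are excluded from the moment summaries
    and counted in ``n_nonconverged``.
    """

    strategy: Strategy
    reps: int
    n_used: int
    mean_beta: float
    bias: float
    empirical_sd: float | None
    mean_model_se: float
    coverage: float
    rejection_rate: float
    truncated_out_mean: float
    n_nonconverged: int


def true_hazard_ratio(design: TrialDesign, treatment_arm: str = "treatment") -> float:
    """Design-implied hazard ratio: treatment vs control post-changepoint rate."""
    trt = [a for a in design.arms if a.name == treatment_arm]
    if len(trt) != 1:
        raise UnsupportedDesignError(f"design needs exactly one {treatment_arm!r} arm")
    controls = [a for a in design.arms if a.name != treatment_arm]
    if not controls:
        raise UnsupportedDesignError("design has no control arm")
    if any(b > design.t1_entry for a in design.arms for b in a.hazard.breakpoints):
        raise UnsupportedDesignError("post-changepoint hazards must be constant")
    control_rates = [a.hazard.final_rate for a in controls]
    if max(control_rates) - min(control_rates) > 1e-12:
        raise UnsupportedDesignError("control arms disagree on the post-changepoint rate")
    return trt[0].hazard.final_rate / control_rates[0]


def run_strategy(
    subjects: Iterable[SubjectRecord],
    t1_entry: float,
    strategy: Strategy | str,
    true_hr: float = math.nan,
    treatment_arm: str = "treatment",
    ties: str = "efron",
) -> StrategyRow:
    """Build the analysis set for one strategy and fit the Cox model."""
    strategy = Strategy(strategy)
    aset = build_analysis_set(subjects, t1_entry, strategy, treatment_arm)
    fit = cox_fit(aset.records, ties=ties)
    return StrategyRow(
        strategy=strategy,
        n_records=len(aset.records),
        n_events=fit.n_events,
        n_truncated_out=aset.n_truncated_out,
        true_hr=true_hr,
        beta=fit.beta,
        hr=fit.hr,
        se=fit.se,
        ci=fit.ci,
        p=fit.p,
        converged=fit.converged,
    )


def comparison_table(
    subjects: Sequence[SubjectRecord],
    t1_entry: float,
    strategies: Sequence[Strategy | str],
    true_hr: float = math.nan,
    treatment_arm: str = "treatment",
    ties: str = "efron",
) -> list[StrategyRow]:
    return [
        run_strategy(subjects, t1_entry, s, true_hr, treatment_arm, ties)
        for s in strategies
    ]


def table_to_frame(rows: Sequence[StrategyRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strategy": [r.strategy.value for r in rows],
            "n_records": [r.n_records for r in rows],
            "n_events": [r.n_events for r in rows],
            "n_truncated_out": [r.n_truncated_out for r in rows],
            "true_hr": [r.true_hr for r in rows],
            "hr": [r.hr for r in rows],
            "se": [r.se for r in rows],
            "ci_low": [r.ci[0] for r in rows],
            "ci_high": [r.ci[1] for r in rows],
            "p": [r.p for r in rows],
            "converged": [r.converged for r in rows],
        }
    )


def exchangeability_check(
    subjects: Iterable[SubjectRecord],
    t1_entry: float,
    treatment_arm: str = "treatment",
) -> LogRankResult:
    """Delayed-entry log-rank between CC and NCC concurrent observation time.

    A small p-value questions the exchangeability assumption behind pooling.
    """
    aset = build_analysis_set(subjects, t1_entry, Strategy.POOLED_COT, treatment_arm)
    cc = [r for r in aset.records if r.origin is Origin.CC]
    ncc = [r for r in aset.records if r.origin is Origin.NCC_COT]
    if not cc or not ncc:
        raise ValueError(
            "exchangeability check needs both CC records "
            f"(got {len(cc)}) and surviving NCC COT records (got {len(ncc)})"
        )
    recs = cc + ncc
    labels = ["CC"] * len(cc) + ["NCC_COT"] * len(ncc)
    return logrank_test(recs, labels)


def monte_carlo(
    design: TrialDesign,
    strategies: Sequence[Strategy | str],
    reps: int,
    seed: int,
    treatment_arm: str = "treatment",
    ties: str = "efron",
    alpha: float = ALPHA,
) -> list[MCSummary]:
    """Operating characteristics of each strategy over ``reps`` replicates.

    Each replicate draws a fresh trial from a deterministic substream of
    ``seed``; coverage is of the 95% Wald CI for the design-implied HR and
    rejection is a two-sided test at ``alpha``.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    strategies = [Strategy(s) for s in strategies]
    true_hr = true_hazard_ratio(design, treatment_arm)
    true_beta = math.log(true_hr)
    acc: dict[Strategy, dict[str, list]] = {
        s: {"beta": [], "se": [], "cover": [], "reject": [], "trunc": [], "bad": 0}
        for s in strategies
    }
    for child in np.random.SeedSequence(seed).spawn(reps):
        subjects = simulate_trial(design, child)
        for s in strategies:
            a = acc[s]
            try:
                row = run_strategy(subjects, design.t1_entry, s, true_hr, treatment_arm, ties)
            except DegenerateCovariateError:
                a["bad"] += 1
                continue
            a["trunc"].append(row.n_truncated_out)
            if not row.converged:
                a["bad"] += 1
                continue
            a["beta"].append(row.beta)
            a["se"].append(row.se)
            a["cover"].append(row.ci[0] <= true_hr <= row.ci[1])
            a["reject"].append(row.p < alpha)
    out = []
    for s in strategies:
        a = acc[s]
        betas = np.asarray(a["beta"], dtype=float)
        n_used = len(betas)
        mean_beta = float(betas.mean()) if n_used else math.nan
        out.append(
            MCSummary(
                strategy=s,
                reps=reps,
                n_used=n_used,
                mean_beta=mean_beta,
                bias=mean_beta - true_beta if n_used else math.nan,
                empirical_sd=float(betas.std(ddof=1)) if n_used >= 2 else None,
                mean_model_se=float(np.mean(a["se"])) if n_used else math.nan,
                coverage=float(np.mean(a["cover"])) if n_used else math.nan,
                rejection_rate=float(np.mean(a["reject"])) if n_used else math.nan,
                truncated_out_mean=float(np.mean(a["trunc"])) if a["trunc"] else 0.0,
                n_nonconverged=a["bad"],
            )
        )
    return out


def mc_to_frame(summaries: Sequence[MCSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strategy": [m.strategy.value for m in summaries],
            "reps": [m.reps for m in summaries],
            "n_used": [m.n_used for m in summaries],
            "mean_beta": [m.mean_beta for m in summaries],
            "bias": [m.bias for m in summaries],
            "empirical_sd": [
                math.nan if m.empirical_sd is None else m.empirical_sd for m in summaries
            ],
            "mean_model_se": [m.mean_model_se for m in summaries],
            "coverage": [m.coverage for m in summaries],
            "rejection_rate": [m.rejection_rate for m in summaries],
            "truncated_out_mean": [m.truncated_out_mean for m in summaries],
            "n_nonconverged": [m.n_nonconverged for m in summaries],
        }
    )
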