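"""Simulation of staggered-entry platform-trial survival data.

Subjects accrue uniformly within per-arm calendar windows, event times are
drawn from piecewise-constant calendar-time hazards by inverting the
cumulative hazard, and follow-up is administratively censored at the
calendar end of study.  Because every hazard segment is exponential, the
calendar-time changepoints can be mapped exactly onto each subject's
time-since-enrollment axis before sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "HazardSpec",
    "ArmSpec",
    "TrialDesign",
    "SubjectRecord",
    "sample_enrollment",
    "patient_scale_changepoint",
    "sample_event_time",
    "invert_piecewise_cumhaz",
    "administrative_censor",
    "simulate_trial",
    "example_design",
]


@dataclass(frozen=True)
class HazardSpec:
    """Piecewise-constant hazard on the calendar time axis.

    ``rates[k]`` applies on ``[breakpoints[k-1], breakpoints[k])``; an empty
    ``breakpoints`` tuple gives a plain exponential (constant) hazard.
    """

    breakpoints: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "breakpoints", tuple(float(b) for b in self.breakpoints))
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))
        if len(self.rates) != len(self.breakpoints) + 1:
            raise ValueError("need exactly one more rate than breakpoints")
        if any(r <= 0 for r in self.rates):
            raise ValueError("hazard rates must be positive")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")

    @classmethod
    def constant(cls, rate: float) -> "HazardSpec":
        return cls((), (rate,))

    @property
    def final_rate(self) -> float:
        """Rate in force after the last breakpoint."""
        return self.rates[-1]

    def rate_at(self, t: float) -> float:
        idx = int(np.searchsorted(self.breakpoints, t, side="right"))
        return self.rates[idx]

    def patient_scale(self, enroll: float) -> tuple[tuple[float, ...], tuple[float, ...]]:
        """Shift the calendar breakpoints onto time-since-enrollment.

        Breakpoints already in the past at enrollment clamp to zero, i.e.
        the subject starts directly in the later regime.
        """
        cuts = tuple(patient_scale_changepoint(enroll, b) for b in self.breakpoints)
        return cuts, self.rates


@dataclass(frozen=True)
class ArmSpec:
    """One trial arm: label, size, accrual window, calendar hazard."""

    name: str
    n: int
    accrual_start: float
    accrual_end: float
    hazard: HazardSpec

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("arm size must be non-negative")
        if self.accrual_start > self.accrual_end:
            raise ValueError("accrual_start must not exceed accrual_end")


@dataclass(frozen=True)
class TrialDesign:
    """Arms plus the new arm's calendar entry time and end of study."""

    arms: tuple[ArmSpec, ...]
    t1_entry: float
    t_max: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "arms", tuple(self.arms))
        if not self.arms:
            raise ValueError("design needs at least one arm")
        lo = min(a.accrual_start for a in self.arms)
        hi = max(a.accrual_end for a in self.arms)
        if not (lo <= self.t1_entry <= hi):
            raise ValueError("t1_entry must lie within the overall accrual window")
        if self.t_max <= hi:
            raise ValueError("t_max must exceed the end of accrual")

    def arm(self, name: str) -> ArmSpec:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(name)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject on the calendar timeline.

    ``followup_time`` is patient-scale time from enrollment to event or
    censoring; ``event`` is True when the event was observed.
    """

    id: str
    arm: str
    enroll: float
    followup_time: float
    event: bool

    def __post_init__(self) -> None:
        if self.followup_time <= 0:
            raise ValueError("followup_time must be positive")


def sample_enrollment(
    n: int, start: float, end: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. uniform enrollment times on ``[start, end]``."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if start > end:
        raise ValueError("start must not exceed end")
    return rng.uniform(start, end, size=n)


def patient_scale_changepoint(enroll: float, t1_entry: float) -> float:
    """Calendar changepoint mapped to a subject's time-since-enrollment axis."""
    return max(0.0, t1_entry - enroll)


def invert_piecewise_cumhaz(
    target: float, cuts: Sequence[float], rates: Sequence[float]
) -> float:
    """Invert the cumulative hazard of a piecewise-constant hazard.

    ``cuts`` are patient-scale segment boundaries (non-decreasing, possibly
    containing 0 for segments already elapsed); ``rates`` has one more entry.
    """
    if target <= 0:
        raise ValueError("cumulative-hazard target must be positive")
    t_prev = 0.0
    acc = 0.0
    for cut, rate in zip(cuts, rates):
        seg = rate * (cut - t_prev)
        if acc + seg >= target:
            return t_prev + (target - acc) / rate
        acc += seg
        t_prev = cut
    return t_prev + (target - acc) / rates[-1]


def sample_event_time(
    cumhaz_target: float, rate_before: float, rate_after: float, changepoint: float
) -> float:
    """Event time for a two-piece hazard with one patient-scale changepoint.

    ``cumhaz_target`` is a realized unit-exponential draw (−ln U); the
    returned time satisfies Λ(t) = cumhaz_target where
    Λ(t) = rate_before·min(t, c) + rate_after·max(0, t − c).
    """
    if cumhaz_target <= 0:
        raise ValueError("cumhaz_target must be positive")
    if rate_before <= 0 or rate_after <= 0:
        raise ValueError("hazard rates must be positive")
    if changepoint < 0:
        raise ValueError("changepoint must be non-negative")
    return invert_piecewise_cumhaz(cumhaz_target, (changepoint,), (rate_before, rate_after))


def administrative_censor(
    event_time: float, enroll: float, t_max: float
) -> tuple[float, bool]:
    """Censor at the calendar end of study.

    Returns ``(followup_time, event)``; an event exactly at the censoring
    boundary counts as observed.
    """
    if enroll >= t_max:
        raise ValueError("enrollment must precede end of study")
    horizon = t_max - enroll
    return min(event_time, horizon), event_time <= horizon


def simulate_trial(
    design: TrialDesign, seed: int | np.random.SeedSequence
) -> list[SubjectRecord]:
    """Simulate all arms of ``design``; same seed gives identical output.

    Each arm draws from its own deterministic substream so arms can be
    regenerated independently of one another.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    records: list[SubjectRecord] = []
    for arm, child in zip(design.arms, ss.spawn(len(design.arms))):
        rng = np.random.default_rng(child)
        enrolls = sample_enrollment(arm.n, arm.accrual_start, arm.accrual_end, rng)
        targets = rng.exponential(size=arm.n)  # -ln U, U ~ Uniform(0,1)
        for i, (enr, tgt) in enumerate(zip(enrolls, targets)):
            cuts, rates = arm.hazard.patient_scale(enr)
            etime = invert_piecewise_cumhaz(tgt, cuts, rates)
            fup, ev = administrative_censor(etime, enr, design.t_max)
            records.append(
                SubjectRecord(f"{arm.name}-{i + 1:05d}", arm.name, float(enr), float(fup), bool(ev))
            )
    return records


def example_design(
    n_ncc: int = 100,
    n_cc: int = 100,
    n_treatment: int = 100,
    base_hazard: float = 0.2,
    log_hazard_shift: float = -0.4,
    treatment_hazard: float | None = 0.114,
    t0: float = 0.0,
    t1_entry: float = 3.0,
    t2: float = 6.0,
    t_max: float = 15.0,
) -> TrialDesign:
    """Three-arm reference design: NCC controls accrue on [t0, t1_entry],
    CC controls and the new treatment on [t1_entry, t2], with the control
    hazard dropping from ``base_hazard`` to ``base_hazard·exp(log_hazard_shift)``
    at the new arm's entry.  Per-arm sizes default to 100 (not dictated by
    the generative model; they control precision only).

    ``treatment_hazard=None`` sets the treatment rate equal to the
    post-changepoint control rate (a null design).
    """
    post_rate = base_hazard * math.exp(log_hazard_shift)
    if treatment_hazard is None:
        treatment_hazard = post_rate
    arms = (
        ArmSpec("ncc_control", n_ncc, t0, t1_entry, HazardSpec((t1_entry,), (base_hazard, post_rate))),
        ArmSpec("cc_control", n_cc, t1_entry, t2, HazardSpec.constant(post_rate)),
        ArmSpec("treatment", n_treatment, t1_entry, t2, HazardSpec.constant(treatment_hazard)),
    )
    return TrialDesign(arms, t1_entry=t1_entry, t_max=t_max)
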