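"""Control classification and left truncation of non-concurrent follow-up.

Controls enrolled before the new arm's entry time are non-concurrent (NCC);
their concurrent observation time is recovered by left truncation: the
subject enters the analysis risk set at L = t1_entry − enroll on the
time-since-randomization scale, and subjects whose follow-up ends at or
before L contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .design import SubjectRecord

__all__ = [
    "ControlClass",
    "Strategy",
    "Origin",
    "AnalysisRecord",
    "AnalysisSet",
    "TRUNCATED_OUT",
    "classify_control",
    "left_truncate",
    "build_analysis_set",
    "records_to_frame",
    "frame_to_records",
]


class ControlClass(Enum):
    CONCURRENT = "concurrent"
    NON_CONCURRENT = "non_concurrent"


class Strategy(Enum):
    """Analysis strategies for the treatment-vs-control comparison."""

    CC_ONLY = "cc_only"
    POOLED_COT = "pooled_cot"
    POOLED_FULL_NCC = "pooled_full_ncc"


class Origin(Enum):
    TREATMENT = "TREATMENT"
    CC = "CC"
    NCC_COT = "NCC_COT"
    NCC_FULL = "NCC_FULL"


class _TruncatedOut:
    """Sentinel: the subject's whole follow-up precedes risk-set entry."""

    def __repr__(self) -> str:  # pragma: no cover
        return "TRUNCATED_OUT"


TRUNCATED_OUT = _TruncatedOut()


@dataclass(frozen=True)
class AnalysisRecord:
    """One subject on the analysis (time-since-randomization) scale.

    Counting-process (entry, exit] convention: the subject is at risk at
    analysis times t with exit >= t > entry.
    """

    id: str
    group: int  # 1 = treatment, 0 = control
    entry: float
    exit: float
    event: bool
    origin: Origin

    def __post_init__(self) -> None:
        if not (0 <= self.entry < self.exit):
            raise ValueError("need 0 <= entry < exit")
        if self.group not in (0, 1):
            raise ValueError("group must be 0 or 1")


@dataclass
class AnalysisSet:
    records: list[AnalysisRecord]
    n_truncated_out: int

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def classify_control(enroll: float, t1_entry: float) -> ControlClass:
    """Non-concurrent iff enrolled strictly before the new arm's entry."""
    if enroll < t1_entry:
        return ControlClass.NON_CONCURRENT
    return ControlClass.CONCURRENT


def left_truncate(subject: SubjectRecord, t1_entry: float):
    """Extract the concurrent observation time of an NCC control.

    Returns an :class:`AnalysisRecord` with entry L = t1_entry − enroll, or
    the :data:`TRUNCATED_OUT` sentinel when follow-up ends at or before L
    (strict ``t > L`` risk-set convention).
    """
    if classify_control(subject.enroll, t1_entry) is not ControlClass.NON_CONCURRENT:
        raise ValueError(f"subject {subject.id!r} is not a non-concurrent control")
    entry = t1_entry - subject.enroll
    if subject.followup_time <= entry:
        return TRUNCATED_OUT
    return AnalysisRecord(
        id=subject.id,
        group=0,
        entry=entry,
        exit=subject.followup_time,
        event=subject.event,
        origin=Origin.NCC_COT,
    )


def build_analysis_set(
    subjects: Iterable[SubjectRecord],
    t1_entry: float,
    strategy: Strategy | str,
    treatment_arm: str = "treatment",
) -> AnalysisSet:
    """Assemble analysis-ready records under one strategy.

    Subjects in ``treatment_arm`` become group 1; all other arms are
    controls, split into CC/NCC by enrollment time.  CC_ONLY drops NCC
    subjects, POOLED_COT keeps their left-truncated concurrent observation
    time, POOLED_FULL_NCC naively keeps their full follow-up from time zero.
    """
    strategy = Strategy(strategy)
    records: list[AnalysisRecord] = []
    n_truncated = 0
    for s in subjects:
        if s.arm == treatment_arm:
            records.append(
                AnalysisRecord(s.id, 1, 0.0, s.followup_time, s.event, Origin.TREATMENT)
            )
        elif classify_control(s.enroll, t1_entry) is ControlClass.CONCURRENT:
            records.append(AnalysisRecord(s.id, 0, 0.0, s.followup_time, s.event, Origin.CC))
        else:  # non-concurrent control
            if strategy is Strategy.CC_ONLY:
                continue
            if strategy is Strategy.POOLED_COT:
                rec = left_truncate(s, t1_entry)
                if rec is TRUNCATED_OUT:
                    n_truncated += 1
                else:
                    records.append(rec)
            else:  # POOLED_FULL_NCC
                records.append(
                    AnalysisRecord(s.id, 0, 0.0, s.followup_time, s.event, Origin.NCC_FULL)
                )
    return AnalysisSet(records, n_truncated)


def records_to_frame(records: Sequence[AnalysisRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "group": [r.group for r in records],
            "entry": [r.entry for r in records],
            "exit": [r.exit for r in records],
            "event": [int(r.event) for r in records],
            "origin": [r.origin.value for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[AnalysisRecord]:
    return [
        AnalysisRecord(
            str(row.id),
            int(row.group),
            float(row.entry),
            float(row.exit),
            bool(row.event),
            Origin(row.origin),
        )
        for row in frame.itertuples(index=False)
    ]
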