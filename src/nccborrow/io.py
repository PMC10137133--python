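"""Config parsing and on-disk formats.

Design configs are YAML; subject and analysis-record tables are plain CSV
(comma-separated, header row, '.' decimal, event coded 0/1).  Subject CSVs
written by the simulator carry the resolved seed in a leading ``#`` comment
line so every output embeds its provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .design import ArmSpec, HazardSpec, SubjectRecord, TrialDesign
from .survival import CoxFit
from .truncation import AnalysisRecord, frame_to_records, records_to_frame

__all__ = [
    "ConfigError",
    "design_from_dict",
    "load_design_yaml",
    "write_subjects_csv",
    "read_subjects_csv",
    "write_records_csv",
    "read_records_csv",
    "fit_to_dict",
    "write_json",
]

SUBJECT_COLUMNS = ["id", "arm", "enroll", "followup_time", "event"]
RECORD_COLUMNS = ["id", "group", "entry", "exit", "event", "origin"]


class ConfigError(ValueError):
    """Malformed configuration or input table."""


def _fmt_float(v) -> str:
    """Shortest round-trip decimal form of a float64."""
    return repr(float(v))


def design_from_dict(cfg: dict) -> tuple[TrialDesign, int | None]:
    """Build a TrialDesign from a parsed YAML mapping; returns (design, seed)."""
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    try:
        arm_cfgs = cfg["arms"]
        t1_entry = float(cfg["t1_entry"])
        t_max = float(cfg["t_max"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"missing or malformed top-level key: {exc}") from exc
    arms = []
    for a in arm_cfgs:
        try:
            hz = a["hazard"]
            spec = HazardSpec(tuple(hz.get("breakpoints", ())), tuple(hz["rates"]))
            arms.append(
                ArmSpec(
                    name=str(a["name"]),
                    n=int(a["n"]),
                    accrual_start=float(a["accrual"][0]),
                    accrual_end=float(a["accrual"][1]),
                    hazard=spec,
                )
            )
        except (KeyError, TypeError, ValueError, IndexError) as exc:
            raise ConfigError(f"malformed arm entry {a!r}: {exc}") from exc
    try:
        design = TrialDesign(tuple(arms), t1_entry=t1_entry, t_max=t_max)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    seed = cfg.get("seed")
    return design, (int(seed) if seed is not None else None)


def load_design_yaml(path) -> tuple[TrialDesign, int | None]:
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    return design_from_dict(cfg)


def subjects_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "arm": [s.arm for s in subjects],
            "enroll": [s.enroll for s in subjects],
            "followup_time": [s.followup_time for s in subjects],
            "event": [int(s.event) for s in subjects],
        }
    )


def write_subjects_csv(subjects: Sequence[SubjectRecord], path, seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        subjects_to_frame(subjects).to_csv(fh, index=False, float_format=_fmt_float)


def read_subjects_csv(path) -> list[SubjectRecord]:
    try:
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ConfigError(f"cannot parse subjects CSV {path}: {exc}") from exc
    missing = set(SUBJECT_COLUMNS) - set(frame.columns)
    if missing:
        raise ConfigError(f"subjects CSV {path} lacks columns: {sorted(missing)}")
    if frame.empty:
        raise ConfigError(f"subjects CSV {path} has no rows")
    return [
        SubjectRecord(
            str(row.id), str(row.arm), float(row.enroll), float(row.followup_time), bool(row.event)
        )
        for row in frame.itertuples(index=False)
    ]


def write_records_csv(records: Sequence[AnalysisRecord], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(path, index=False, float_format=_fmt_float)


def read_records_csv(path) -> list[AnalysisRecord]:
    try:
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ConfigError(f"cannot parse records CSV {path}: {exc}") from exc
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise ConfigError(f"records CSV {path} lacks columns: {sorted(missing)}")
    if frame.empty:
        raise ConfigError(f"records CSV {path} has no rows")
    return frame_to_records(frame)


def fit_to_dict(fit: CoxFit) -> dict:
    return {
        "beta": fit.beta,
        "se": fit.se,
        "hr": fit.hr,
        "ci": [fit.ci[0], fit.ci[1]],
        "p": fit.p,
        "loglik": fit.loglik,
        "n": fit.n,
        "events": fit.n_events,
        "converged": fit.converged,
    }


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
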