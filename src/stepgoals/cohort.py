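"""Data model for an ABAB (reversal-design) step-count study.

A cohort is a long table of daily step counts, one row per child per
school day.  The study design partitions the day axis into alternating
baseline (A) and intervention/"game" (B) phases; the default design is
four 10-day phases over 40 consecutive school days.  This module owns
record ingestion/validation, phase assignment, and the per-child
aggregations (phase medians, condition totals) that the statistics
consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
import yaml

__all__ = [
    "StepRecord",
    "Phase",
    "StudyDesign",
    "StepDataError",
    "read_records",
    "write_records",
    "filter_nonwear",
    "assign_phase",
    "child_phase_median",
    "condition_totals",
    "child_phase_summaries",
]

#: canonical long-format CSV columns
RECORD_COLUMNS = ("child_id", "day", "steps")

BASELINE = "baseline"
GAME = "game"


class StepDataError(ValueError):
    """Malformed or inconsistent step-count data."""


class StepRecord(NamedTuple):
    """One child's total step count on one school day (1-based day index)."""

    child_id: str
    day: int
    steps: int


@dataclass(frozen=True)
class Phase:
    """One contiguous block of study days under a single condition."""

    label: str
    condition: str  # "baseline" or "game"
    start: int  # inclusive, 1-based
    end: int  # inclusive

    @property
    def days(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class StudyDesign:
    """Ordered phase plan mapping study days 1..D to condition labels.

    Phases must be contiguous, non-overlapping, and cover 1..D with no
    gaps.  The default is the standard two-week ABAB plan: baseline1
    (days 1-10), game1 (11-20), baseline2 (21-30), game2 (31-40).
    """

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("design must contain at least one phase")
        expected_start = 1
        for ph in self.phases:
            if ph.condition not in (BASELINE, GAME):
                raise ValueError(f"unknown condition {ph.condition!r}")
            if ph.start != expected_start:
                raise ValueError(
                    f"phase {ph.label!r} starts on day {ph.start}, "
                    f"expected {expected_start} (phases must be contiguous)"
                )
            if ph.end < ph.start:
                raise ValueError(f"phase {ph.label!r} has empty day range")
            expected_start = ph.end + 1
        labels = [ph.label for ph in self.phases]
        if len(set(labels)) != len(labels):
            raise ValueError("phase labels must be unique")

    @classmethod
    def default(cls) -> "StudyDesign":
        return cls(
            (
                Phase("baseline1", BASELINE, 1, 10),
                Phase("game1", GAME, 11, 20),
                Phase("baseline2", BASELINE, 21, 30),
                Phase("game2", GAME, 31, 40),
            )
        )

    @property
    def n_days(self) -> int:
        return self.phases[-1].end

    @property
    def labels(self) -> list[str]:
        return [ph.label for ph in self.phases]

    def phase(self, label: str) -> Phase:
        for ph in self.phases:
            if ph.label == label:
                return ph
        raise KeyError(f"no phase labelled {label!r}")

    def assign(self, day: int) -> Phase:
        """Phase containing ``day``; raises for days outside the design."""
        for ph in self.phases:
            if ph.start <= day <= ph.end:
                return ph
        raise ValueError(f"day {day} outside study design (1..{self.n_days})")

    def condition_days(self, condition: str) -> list[int]:
        return [d for ph in self.phases if ph.condition == condition for d in ph.days]

    def is_game_day(self, day: int) -> bool:
        return self.assign(day).condition == GAME

    # -- serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "phases": [
                {"label": p.label, "condition": p.condition, "start": p.start, "end": p.end}
                for p in self.phases
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        return cls(
            tuple(
                Phase(p["label"], p["condition"], int(p["start"]), int(p["end"]))
                for p in d["phases"]
            )
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def assign_phase(day: int, design: StudyDesign) -> str:
    """Label of the phase containing ``day`` (error outside the design)."""
    return design.assign(day).label


# ---------------------------------------------------------------------
# record I/O
# ---------------------------------------------------------------------

def _validate_records(df: pd.DataFrame, *, line_offset: int = 2) -> pd.DataFrame:
    """Validate a records frame; line numbers assume a CSV header row."""
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise StepDataError(f"missing columns: {sorted(missing)}")
    df = df.loc[:, list(RECORD_COLUMNS)].copy()

    for col in ("day", "steps"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            lines = [i + line_offset for i in df.index[bad][:5]]
            raise StepDataError(f"non-integer {col!r} values at lines {lines}")
        df[col] = numeric.astype(int)

    neg = df["steps"] < 0
    if neg.any():
        lines = [i + line_offset for i in df.index[neg][:5]]
        raise StepDataError(f"negative step counts at lines {lines}")
    if (df["day"] < 1).any():
        lines = [i + line_offset for i in df.index[df["day"] < 1][:5]]
        raise StepDataError(f"day indices must be >= 1; bad lines {lines}")

    dup = df.duplicated(subset=["child_id", "day"], keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        lines = [i + line_offset for i in df.index[dup][:5]]
        raise StepDataError(
            f"duplicate (child_id, day) pair ({first.child_id!r}, day {first.day}) "
            f"at lines {lines}"
        )
    df["child_id"] = df["child_id"].astype(str)
    return df.sort_values(["child_id", "day"], kind="stable").reset_index(drop=True)


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a long-format cohort CSV (columns ``child_id,day,steps``).

    Malformed rows (negative steps, non-integer day, duplicate child/day
    pairs) are rejected with the offending line numbers.
    """
    try:
        df = pd.read_csv(path, dtype={"child_id": str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise StepDataError(f"cannot read records from {path}: {exc}") from exc
    return _validate_records(df)


def write_records(records: pd.DataFrame | Iterable[StepRecord], path: str | Path) -> None:
    """Write records to CSV; ``read_records`` round-trips the output."""
    df = as_frame(records)
    df.to_csv(path, index=False)


def as_frame(records: pd.DataFrame | Iterable[StepRecord]) -> pd.DataFrame:
    """Coerce records (frame or iterable of StepRecord) to a validated frame."""
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records), columns=RECORD_COLUMNS)
    return _validate_records(records)


def filter_nonwear(records: pd.DataFrame, min_steps: int = 1) -> pd.DataFrame:
    """Drop child-days below ``min_steps`` (0 steps read as device not worn)."""
    return records[records["steps"] >= min_steps].reset_index(drop=True)


# ---------------------------------------------------------------------
# per-child aggregation
# ---------------------------------------------------------------------

def child_phase_median(records: pd.DataFrame, child_id: str, phase: str,
                       design: StudyDesign | None = None) -> float:
    """Median of one child's daily steps within one phase.

    The median runs over the days the child is present; a child with no
    records in the phase is an error.
    """
    design = design or StudyDesign.default()
    ph = design.phase(phase)
    sub = records[
        (records["child_id"] == str(child_id))
        & records["day"].between(ph.start, ph.end)
    ]
    if sub.empty:
        raise StepDataError(f"child {child_id!r} has no records in phase {phase!r}")
    return float(sub["steps"].median())


def condition_totals(records: pd.DataFrame, child_id: str,
                     design: StudyDesign | None = None) -> tuple[int, int]:
    """(baseline total, game total) step sums for one child."""
    design = design or StudyDesign.default()
    sub = records[records["child_id"] == str(child_id)]
    if sub.empty:
        raise StepDataError(f"no records for child {child_id!r}")
    cond = sub["day"].map(lambda d: design.assign(int(d)).condition)
    base = int(sub.loc[cond == BASELINE, "steps"].sum())
    game = int(sub.loc[cond == GAME, "steps"].sum())
    return base, game


def child_phase_summaries(records: pd.DataFrame,
                          design: StudyDesign | None = None) -> pd.DataFrame:
    """Per-child summary table: one row per child.

    Columns: ``child_id``, ``median_<phase>`` for each phase label, and
    ``total_baseline`` / ``total_game`` condition sums.  These are the
    paired observations entering the signed-rank contrasts and the
    all-children-increased binomial test.
    """
    design = design or StudyDesign.default()
    records = as_frame(records)
    rows = []
    for child, sub in records.groupby("child_id", sort=True):
        row: dict = {"child_id": child}
        for ph in design.phases:
            inphase = sub[sub["day"].between(ph.start, ph.end)]
            if inphase.empty:
                raise StepDataError(
                    f"child {child!r} has no records in phase {ph.label!r}"
                )
            row[f"median_{ph.label}"] = float(inphase["steps"].median())
        base, game = condition_totals(sub, child, design)
        row["total_baseline"] = base
        row["total_game"] = game
        rows.append(row)
    return pd.DataFrame(rows)
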