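"""Percentile schedule of reinforcement for class-level step goals.

The schedule sets each intervention day's goal at a fixed percentile
(default the 60th) of the class's median daily step counts over a moving
window of the preceding days (default 10).  The class meets the goal
when today's median-per-child step count is *at or above* the goal;
meeting the goal on day X releases the next narrative episode on day
X+1.  Because the window moves, goal difficulty tracks current
performance: sustained success raises the goal, failure lowers it —
no separate adjustment rule is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .cohort import GAME, StudyDesign

__all__ = [
    "ScheduleParams",
    "DailyOutcome",
    "daily_median",
    "percentile_of",
    "compute_goal",
    "evaluate_goal",
    "run_schedule",
    "daily_medians_from_records",
    "outcomes_to_frame",
    "write_outcomes",
    "read_outcomes",
]

INTERPOLATIONS = ("linear", "nearest_rank")


@dataclass(frozen=True)
class ScheduleParams:
    """Parameters of the percentile schedule.

    window_size
        Number of preceding study days whose daily medians form the
        goal window (default 10; must be >= 1).
    percentile
        Percentile level as a fraction in (0, 1); default 0.60.
    interpolation
        ``"linear"``: index h = 1 + p(n-1) into the sorted window with
        linear interpolation between adjacent order statistics.
        ``"nearest_rank"``: the ceil(p*n)-th order statistic, the
        convention of classical behaviour-analysis percentile schedules.
    """

    window_size: int = 10
    percentile: float = 0.60
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not 0.0 < self.percentile < 1.0:
            raise ValueError("percentile must lie strictly in (0, 1)")
        if self.interpolation not in INTERPOLATIONS:
            raise ValueError(f"interpolation must be one of {INTERPOLATIONS}")


@dataclass(frozen=True)
class DailyOutcome:
    """Schedule state for one study day.

    ``goal`` and ``met`` are ``None`` on baseline days (no goal is in
    force).  ``episode_released`` refers to presentation on this day,
    earned by meeting the goal on the most recent preceding game day.
    """

    day: int
    phase: str
    daily_median: float
    goal: float | None
    met: bool | None
    episode_released: bool


def daily_median(steps_today: Sequence[float]) -> float:
    """Median-per-child step count for one day.

    Midpoint of the two central order statistics for even counts.  A day
    with no observations is an error.
    """
    values = sorted(steps_today)
    n = len(values)
    if n == 0:
        raise ValueError("no step observations for this day")
    if any(v < 0 for v in values):
        raise ValueError("step counts must be non-negative")
    mid = n // 2
    if n % 2:
        return float(values[mid])
    return (values[mid - 1] + values[mid]) / 2.0


def percentile_of(values: Sequence[float], p: float,
                  interpolation: str = "linear") -> float:
    """p-th percentile (p a fraction in (0,1)) of ``values``.

    linear: h = 1 + p(n-1), interpolating between adjacent order
    statistics (the result for p=0.6 over {1..10} is 6.4).
    nearest_rank: the ceil(p*n)-th order statistic.  Either way the
    result lies within [min, max] of the sample.
    """
    if len(values) == 0:
        raise ValueError("cannot take a percentile of an empty sample")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly in (0, 1)")
    v = sorted(values)
    n = len(v)
    if interpolation == "linear":
        h = 1.0 + p * (n - 1)
        lo = int(math.floor(h))
        frac = h - lo
        if lo >= n:
            return float(v[-1])
        return float(v[lo - 1] + frac * (v[lo] - v[lo - 1]))
    if interpolation == "nearest_rank":
        k = math.ceil(p * n)
        return float(v[k - 1])
    raise ValueError(f"interpolation must be one of {INTERPOLATIONS}")


def compute_goal(window: Sequence[float], params: ScheduleParams) -> float:
    """Goal from the last ``window_size`` daily medians.

    The window is strictly the most recent ``window_size`` study days,
    regardless of which phases those days belonged to; a short window
    means the goal is undefined.
    """
    if len(window) != params.window_size:
        raise ValueError(
            f"goal undefined: window has {len(window)} days, "
            f"need exactly {params.window_size}"
        )
    return percentile_of(window, params.percentile, params.interpolation)


def evaluate_goal(daily_median_value: float, goal: float) -> bool:
    """True iff the day's median is at or above the goal (inclusive)."""
    return daily_median_value >= goal


def run_schedule(daily_medians: Sequence[float], design: StudyDesign,
                 params: ScheduleParams | None = None) -> list[DailyOutcome]:
    """Run the percentile schedule over consecutive study days 1..D.

    ``daily_medians[d-1]`` is the class median on day d.  On each game
    day the goal is the schedule percentile of the preceding
    ``window_size`` days' medians (baseline days count when they fall in
    the window); baseline days carry no goal.  An episode is released on
    a game day iff the most recent preceding game day met its goal.
    """
    params = params or ScheduleParams()
    if len(daily_medians) != design.n_days:
        raise ValueError(
            f"need one daily median per design day: got {len(daily_medians)}, "
            f"design covers {design.n_days}"
        )
    outcomes: list[DailyOutcome] = []
    last_game_met: bool | None = None  # met flag of the most recent game day
    for day in range(1, design.n_days + 1):
        phase = design.assign(day)
        median = float(daily_medians[day - 1])
        if phase.condition == GAME:
            if day <= params.window_size:
                raise ValueError(
                    f"game day {day} has fewer than {params.window_size} prior days"
                )
            window = [float(m) for m in daily_medians[day - 1 - params.window_size: day - 1]]
            goal = compute_goal(window, params)
            met = evaluate_goal(median, goal)
            released = bool(last_game_met)
            last_game_met = met
        else:
            goal = None
            met = None
            released = False
        outcomes.append(DailyOutcome(day, phase.label, median, goal, met, released))
    return outcomes


def daily_medians_from_records(records: pd.DataFrame,
                               design: StudyDesign) -> list[float]:
    """Class daily medians (over children present each day) for days 1..D."""
    medians = []
    for day in range(1, design.n_days + 1):
        today = records.loc[records["day"] == day, "steps"]
        if today.empty:
            raise ValueError(f"day {day} has no step observations")
        medians.append(daily_median(today.tolist()))
    return medians


# ---------------------------------------------------------------------
# outcome I/O — CSV with empty strings for absent goal/met
# ---------------------------------------------------------------------

def outcomes_to_frame(outcomes: Sequence[DailyOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "day": [o.day for o in outcomes],
            "phase": [o.phase for o in outcomes],
            "daily_median": [o.daily_median for o in outcomes],
            "goal": [o.goal for o in outcomes],
            "met": [o.met for o in outcomes],
            "episode_released": [o.episode_released for o in outcomes],
        }
    )


def write_outcomes(outcomes: Sequence[DailyOutcome], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "day": [o.day for o in outcomes],
            "phase": [o.phase for o in outcomes],
            "daily_median": [repr(float(o.daily_median)) for o in outcomes],
            "goal": ["" if o.goal is None else repr(float(o.goal)) for o in outcomes],
            "met": ["" if o.met is None else str(bool(o.met)) for o in outcomes],
            "episode_released": [str(bool(o.episode_released)) for o in outcomes],
        }
    )
    df.to_csv(path, index=False)


def read_outcomes(path: str | Path) -> list[DailyOutcome]:
    df = pd.read_csv(path, keep_default_na=False, dtype=str)
    outcomes = []
    for row in df.itertuples(index=False):
        goal = None if row.goal == "" else float(row.goal)
        met = None if row.met == "" else (str(row.met) == "True")
        outcomes.append(
            DailyOutcome(
                int(row.day), str(row.phase), float(row.daily_median),
                goal, met, str(row.episode_released) == "True",
            )
        )
    return outcomes
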