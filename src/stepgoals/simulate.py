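"""Closed-loop synthetic classroom under the percentile schedule.

No raw per-child accelerometer data accompany published classroom
goal-setting studies of this kind, so testing the full pipeline needs a
generator that reproduces the *structure* the analysis assumes:
child-level heterogeneity, day-to-day noise, an additive intervention
effect on game days, and the feedback loop in which each day's class
median feeds the moving-window goal and a missed goal can raise
next-day effort.  Child i's emitted steps on day d are

    steps = max(0, round(mu_i + game_d * (delta + gamma * miss) + eps_id))

with mu_i ~ Normal(mu_mean, mu_sd) drawn once per child,
eps_id ~ Normal(0, eps_sd) fresh each day, game_d the game-day
indicator, and miss the indicator that the most recent preceding game
day's goal was missed.  The defaults target the magnitudes of a 29-child
classroom stepping ~3300/day at baseline with an ~800-step game uplift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import GAME, StudyDesign
from .schedule import (
    DailyOutcome,
    ScheduleParams,
    compute_goal,
    daily_median,
    evaluate_goal,
)
from .stats import run_analysis

__all__ = ["SimParams", "simulate_cohort", "estimate_uplift", "recover_effect"]


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of the synthetic classroom.

    mu_mean / mu_sd : steps
        Mean and between-child SD of the per-child baseline level.
    eps_sd : steps
        Within-child day-to-day SD.
    delta : steps
        Additive class-wide effect on game days.
    gamma : steps
        Feedback gain: extra class-wide effort on a game day that
        follows a missed goal.  0 keeps the no-effect null analytically
        checkable; positive values push goal attainment above the
        stationary moving-window level.
    """

    n_children: int = 29
    n_days: int = 40
    mu_mean: float = 3300.0
    mu_sd: float = 600.0
    eps_sd: float = 500.0
    delta: float = 800.0
    gamma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ValueError("need at least one child")
        if min(self.mu_sd, self.eps_sd) < 0:
            raise ValueError("standard deviations must be non-negative")


def simulate_cohort(
    params: SimParams | None = None,
    schedule: ScheduleParams | None = None,
    design: StudyDesign | None = None,
) -> tuple[pd.DataFrame, list[DailyOutcome]]:
    """Simulate one classroom day by day under the percentile schedule.

    Returns the long-format records frame and the schedule's daily
    outcomes.  The loop is closed: after each day the class median is
    appended to the window, and on game days the goal/met state drives
    both episode release and (through ``gamma``) the next game day's
    effort.  A fixed seed gives bit-identical output.
    """
    params = params or SimParams()
    schedule = schedule or ScheduleParams()
    design = design or StudyDesign.default()
    if design.n_days != params.n_days:
        raise ValueError(
            f"design covers {design.n_days} days but n_days={params.n_days}"
        )
    first_game = min(
        (ph.start for ph in design.phases if ph.condition == GAME), default=None
    )
    if first_game is not None and first_game <= schedule.window_size:
        raise ValueError(
            f"first game day {first_game} falls inside the initial "
            f"{schedule.window_size}-day window"
        )

    rng = np.random.default_rng(params.seed)
    mu = rng.normal(params.mu_mean, params.mu_sd, size=params.n_children)

    child_ids = [f"c{i + 1:02d}" for i in range(params.n_children)]
    rows: list[tuple[str, int, int]] = []
    medians: list[float] = []
    outcomes: list[DailyOutcome] = []
    last_game_met: bool | None = None

    for day in range(1, params.n_days + 1):
        phase = design.assign(day)
        is_game = phase.condition == GAME
        missed_prev = 1.0 if (is_game and last_game_met is False) else 0.0
        effect = (params.delta + params.gamma * missed_prev) if is_game else 0.0
        eps = rng.normal(0.0, params.eps_sd, size=params.n_children)
        steps = np.maximum(0, np.rint(mu + effect + eps)).astype(int)
        rows.extend(zip(child_ids, [day] * params.n_children, steps.tolist()))

        median = daily_median(steps.tolist())
        medians.append(median)
        if is_game:
            window = medians[day - 1 - schedule.window_size: day - 1]
            goal = compute_goal(window, schedule)
            met = evaluate_goal(median, goal)
            released = bool(last_game_met)
            last_game_met = met
        else:
            goal, met, released = None, None, False
        outcomes.append(DailyOutcome(day, phase.label, median, goal, met, released))

    records = pd.DataFrame(rows, columns=["child_id", "day", "steps"])
    return records, outcomes


def estimate_uplift(records: pd.DataFrame, design: StudyDesign | None = None) -> float:
    """Median across children of (game-condition median - baseline median).

    The per-child difference of condition medians is a robust estimate
    of the additive game effect; its median over children estimates
    ``delta`` without bias under the symmetric generative model.
    """
    design = design or StudyDesign.default()
    diffs = []
    for _, sub in records.groupby("child_id"):
        by_cond = {}
        for cond in ("baseline", "game"):
            days = design.condition_days(cond)
            vals = sub.loc[sub["day"].isin(days), "steps"]
            by_cond[cond] = float(vals.median())
        diffs.append(by_cond["game"] - by_cond["baseline"])
    return float(np.median(diffs))


def recover_effect(
    deltas: Sequence[float],
    n_reps: int = 200,
    seed: int = 0,
    params: SimParams | None = None,
    schedule: ScheduleParams | None = None,
    design: StudyDesign | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pipeline validation sweep over a grid of game effects.

    For each ``delta``, simulates ``n_reps`` cohorts, runs the full
    analysis, and records the fraction of replicates in which all four
    adjacent/reversal contrasts (baseline1-game1, game1-baseline2,
    baseline2-game2, baseline1-game2) are significant at the
    Bonferroni-corrected alpha, together with the mean estimated uplift.

    Returns a frame with columns ``delta``, ``power``, ``mean_uplift``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    params = params or SimParams()
    design = design or StudyDesign.default()
    focal = [("baseline1", "game1"), ("game1", "baseline2"),
             ("baseline2", "game2"), ("baseline1", "game2")]
    seed_rng = np.random.default_rng(seed)
    out = []
    for delta in deltas:
        hits = 0
        uplifts = []
        for _ in range(n_reps):
            p = replace(params, delta=float(delta),
                        seed=int(seed_rng.integers(0, 2**31 - 1)))
            records, _ = simulate_cohort(p, schedule, design)
            results = run_analysis(records, design, alpha=alpha, method="normal")
            sig = {frozenset((c.phase_a, c.phase_b)): c.significant
                   for c in results.comparisons}
            if all(sig.get(frozenset(pair), False) for pair in focal):
                hits += 1
            uplifts.append(estimate_uplift(records, design))
        out.append(
            {"delta": float(delta), "power": hits / n_reps,
             "mean_uplift": float(np.mean(uplifts))}
        )
    return pd.DataFrame(out)
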