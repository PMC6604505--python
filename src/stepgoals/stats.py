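"""Nonparametric analysis chain for ABAB single-case step-count studies.

The chain mirrors standard practice for small-n repeated-measures data
that fail a normality check: a Shapiro-Wilk gate per condition, a
Friedman omnibus test over the k phase medians, Bonferroni-corrected
pairwise Wilcoxon matched-pairs signed-rank post hocs with effect sizes
r = Z / sqrt(N) (N = total observations across the two paired
conditions, i.e. 2 * n_pairs), and an exact binomial test of whether
every child stepped more under the intervention condition.

The Wilcoxon statistic follows the signed-rank-sum convention:

    W = (sum of positive ranks) - (sum of negative ranks),

ranging over [-n(n+1)/2, n(n+1)/2], with zero differences dropped before
ranking, mid-ranks on tied |differences|, a tie-corrected normal
variance, and no continuity correction.  For small effective n the
two-sided p comes from exact enumeration of all 2^n sign patterns.

The object-style entry point is :class:`PhaseReversalModel`, whose
``fit`` returns a :class:`PhaseReversalResults` carrying the full report
(statsmodels-style); :func:`run_analysis` is the one-call convenience
wrapper.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import (
    BASELINE,
    GAME,
    StepDataError,
    StudyDesign,
    as_frame,
    child_phase_summaries,
    filter_nonwear,
)

__all__ = [
    "ShapiroGate",
    "WilcoxonResult",
    "PhaseComparison",
    "PhaseReversalModel",
    "PhaseReversalResults",
    "shapiro_gate",
    "friedman_test",
    "wilcoxon_signed_rank",
    "signed_rank_z",
    "effect_size_r",
    "bonferroni_alpha",
    "all_increase_binomial",
    "run_analysis",
]

#: largest effective n for which the exact sign-pattern enumeration is used
EXACT_N_MAX = 12


# ---------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class ShapiroGate:
    statistic: float
    p: float
    normal: bool  # p >= 0.05


def shapiro_gate(values: Sequence[float], alpha: float = 0.05) -> ShapiroGate:
    """Shapiro-Wilk normality check on one condition's per-child medians.

    ``normal`` is False when p < ``alpha``; the pipeline proceeds
    nonparametrically when any condition fails the gate.  A constant
    sample leaves the statistic undefined and is an error.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = sps.shapiro(arr)
    return ShapiroGate(float(w), float(p), bool(p >= alpha))


def friedman_test(matrix: np.ndarray | Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Friedman rank test over an n-subjects x k-treatments matrix.

    Rows are ranked with mid-ranks;

        chi2 = [12 / (n k (k+1))] * sum_j R_j^2 - 3 n (k+1),

    divided by the standard tie-correction factor
    1 - sum(t^3 - t) / (n k (k^2 - 1)).  Returns (chi2, df=k-1, upper
    tail chi-square p).  Missing cells are an error; no imputation.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("need an n x k matrix of phase values")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("Friedman test needs n >= 2 subjects and k >= 2 treatments")
    if np.isnan(m).any():
        raise ValueError("missing cells are not allowed (no imputation)")

    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)

    # tie correction: per row, sum over tie groups of t^3 - t
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0:
        raise ValueError("all rows constant: Friedman statistic undefined")
    chi2 /= correction

    df = k - 1
    p = float(sps.chi2.sf(chi2, df))
    return float(chi2), df, p


def signed_rank_z(w: float, n: int, tie_term: float = 0.0) -> float:
    """Normal deviate for a signed-rank sum W over n nonzero pairs.

    Var(W) = n(n+1)(2n+1)/6 - tie_term/12 where tie_term is
    sum(t^3 - t) over groups of tied |differences|.  No continuity
    correction.
    """
    if n < 1:
        raise ValueError("need at least one nonzero difference")
    var = n * (n + 1) * (2 * n + 1) / 6.0 - tie_term / 12.0
    if var <= 0:
        raise ValueError("degenerate variance (all differences tied at one value)")
    return float(w / math.sqrt(var))


@dataclass(frozen=True)
class WilcoxonResult:
    n_pairs: int  # effective pairs after dropping zero differences
    W: float  # signed-rank sum (positive minus negative ranks)
    Z: float
    p: float
    method: str  # "exact" or "normal"


def _exact_signed_rank_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided P(|W| >= |w_obs|) by enumerating all sign patterns.

    ``ranks`` are the (mid-)ranks of the absolute differences; under the
    null every difference is independently positive or negative with
    probability 1/2.
    """
    n = len(ranks)
    total = ranks.sum()
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        pos = sum(r for s, r in zip(signs, ranks) if s)
        w = 2 * pos - total
        if abs(w) >= abs(w_obs) - 1e-9:
            count += 1
    return count / 2.0**n


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float],
                         method: str = "auto") -> WilcoxonResult:
    """Wilcoxon matched-pairs signed-rank test on differences y - x.

    Zero differences are dropped (reducing effective n); tied absolute
    differences receive mid-ranks.  ``method`` is ``"exact"`` (full
    enumeration), ``"normal"`` (tie-corrected normal approximation
    without continuity correction), or ``"auto"`` (exact when effective
    n <= 12).  All-zero differences leave the test undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    d = y - x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero: test undefined")

    ranks = sps.rankdata(np.abs(d))
    w = float(np.sum(np.sign(d) * ranks))

    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    z = signed_rank_z(w, n, tie_term)

    if method == "auto":
        method = "exact" if n <= EXACT_N_MAX else "normal"
    if method == "exact":
        p = _exact_signed_rank_p(ranks, w)
    elif method == "normal":
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        raise ValueError("method must be 'auto', 'exact' or 'normal'")
    return WilcoxonResult(int(n), w, z, min(p, 1.0), method)


def effect_size_r(z: float, n_pairs: int) -> float:
    """Rank-test effect size r = Z / sqrt(N) with N = 2 * n_pairs.

    N counts the total observations across both paired conditions.
    Conventional benchmarks: 0.1 small, 0.3 medium, 0.5 large.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    return float(z / math.sqrt(2 * n_pairs))


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-comparison alpha = family_alpha / m, reported to 4 decimals."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return round(family_alpha / m, 4)


def all_increase_binomial(summaries: pd.DataFrame) -> tuple[int, int, float]:
    """Exact binomial test that children step more under the game condition.

    A success is ``total_game > total_baseline``; exact ties are
    excluded from the trials (a tie is evidence for neither direction).
    Two-sided p at p0 = 0.5 by the minimum-likelihood method.
    """
    diffs = summaries["total_game"] - summaries["total_baseline"]
    trials = int((diffs != 0).sum())
    successes = int((diffs > 0).sum())
    if trials == 0:
        raise ValueError("every child has identical condition totals")
    p = float(sps.binomtest(successes, trials, 0.5).pvalue)
    return successes, trials, p


# ---------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseComparison:
    """One paired phase contrast from the post-hoc family."""

    phase_a: str
    phase_b: str
    n_pairs: int
    W: float
    Z: float
    p: float
    r: float
    significant: bool  # at the Bonferroni-corrected alpha
    method: str = "normal"

    def to_dict(self) -> dict:
        return {
            "phase_a": self.phase_a, "phase_b": self.phase_b,
            "n_pairs": self.n_pairs, "W": self.W, "Z": self.Z,
            "p": self.p, "r": self.r, "significant": self.significant,
            "method": self.method,
        }


class PhaseReversalModel:
    """Nonparametric ABAB reversal analysis of a step-count cohort.

    Parameters
    ----------
    records
        Long-format cohort (``child_id``, ``day``, ``steps``) as a
        DataFrame or iterable of :class:`~stepgoals.cohort.StepRecord`.
    design
        Phase plan; defaults to the 4 x 10-day ABAB design.
    alpha
        Family-wise error rate for the post-hoc family (default 0.05,
        split over all pairwise phase contrasts).
    drop_nonwear
        Drop child-days with 0 steps before analysis (a zero reads as
        the device not being worn).

    ``fit()`` runs the whole chain and returns
    :class:`PhaseReversalResults`.
    """

    def __init__(self, records, design: StudyDesign | None = None, *,
                 alpha: float = 0.05, drop_nonwear: bool = True) -> None:
        self.design = design or StudyDesign.default()
        records = as_frame(records)
        if drop_nonwear:
            records = filter_nonwear(records)
        self.records = records
        self.alpha = float(alpha)

    @classmethod
    def from_csv(cls, path: str | Path, design: StudyDesign | None = None,
                 **kwargs) -> "PhaseReversalModel":
        from .cohort import read_records
        return cls(read_records(path), design, **kwargs)

    def fit(self, method: str = "auto") -> "PhaseReversalResults":
        """Run gate -> Friedman omnibus -> Wilcoxon post hocs -> binomial.

        ``method`` selects the Wilcoxon p-value route (see
        :func:`wilcoxon_signed_rank`).
        """
        design = self.design
        summaries = child_phase_summaries(self.records, design)
        labels = design.labels
        median_cols = [f"median_{lab}" for lab in labels]

        # normality gate per condition: each child's median daily steps
        # pooled over all of that condition's days
        condition_child_medians: dict[str, pd.Series] = {}
        for condition in (BASELINE, GAME):
            days = design.condition_days(condition)
            if not days:
                continue
            sub = self.records[self.records["day"].isin(days)]
            condition_child_medians[condition] = (
                sub.groupby("child_id")["steps"].median().astype(float)
            )
        shapiro = {cond: shapiro_gate(vals)
                   for cond, vals in condition_child_medians.items()}

        chi2, df, friedman_p = friedman_test(summaries[median_cols].to_numpy())

        pairs = list(itertools.combinations(labels, 2))
        corrected = bonferroni_alpha(self.alpha, len(pairs))
        comparisons = []
        for a, b in pairs:
            res = wilcoxon_signed_rank(summaries[f"median_{a}"],
                                       summaries[f"median_{b}"], method=method)
            r = effect_size_r(res.Z, res.n_pairs)
            comparisons.append(
                PhaseComparison(a, b, res.n_pairs, res.W, res.Z, res.p, r,
                                bool(res.p < corrected), res.method)
            )

        successes, trials, binom_p = all_increase_binomial(summaries)
        phase_medians = {lab: float(summaries[f"median_{lab}"].median())
                         for lab in labels}
        condition_medians = {cond: float(vals.median())
                             for cond, vals in condition_child_medians.items()}

        return PhaseReversalResults(
            model=self, summaries=summaries, shapiro=shapiro,
            friedman_chi2=chi2, friedman_df=df, friedman_p=friedman_p,
            comparisons=comparisons, corrected_alpha=corrected,
            binomial=(successes, trials, binom_p),
            phase_medians=phase_medians, condition_medians=condition_medians,
        )


@dataclass
class PhaseReversalResults:
    """Fitted ABAB analysis: omnibus, contrasts, effect sizes, binomial."""

    model: PhaseReversalModel
    summaries: pd.DataFrame
    shapiro: dict[str, ShapiroGate]
    friedman_chi2: float
    friedman_df: int
    friedman_p: float
    comparisons: list[PhaseComparison]
    corrected_alpha: float
    binomial: tuple[int, int, float]
    phase_medians: dict[str, float]
    condition_medians: dict[str, float] = field(default_factory=dict)

    @property
    def nonparametric_justified(self) -> bool:
        """True when any condition fails the normality gate."""
        return any(not g.normal for g in self.shapiro.values())

    def comparisons_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_dict() for c in self.comparisons])

    def to_dict(self) -> dict:
        return {
            "design": self.model.design.to_dict(),
            "alpha": self.model.alpha,
            "corrected_alpha": self.corrected_alpha,
            "shapiro": {
                cond: {"statistic": g.statistic, "p": g.p, "normal": g.normal}
                for cond, g in self.shapiro.items()
            },
            "friedman": {"chi2": self.friedman_chi2, "df": self.friedman_df,
                         "p": self.friedman_p},
            "comparisons": [c.to_dict() for c in self.comparisons],
            "binomial": {"successes": self.binomial[0],
                         "trials": self.binomial[1],
                         "p": self.binomial[2]},
            "phase_medians": self.phase_medians,
            "condition_medians": self.condition_medians,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary(self) -> str:
        """Results-paragraph-style text summary at conventional precision
        (W as printed, r to 3 decimals, alpha to 4)."""
        lines = ["ABAB phase-reversal analysis", "=" * 32]
        n = len(self.summaries)
        lines.append(f"children: {n}; phases: {', '.join(self.phase_medians)}")
        for cond, g in self.shapiro.items():
            verdict = "normal" if g.normal else "non-normal"
            lines.append(
                f"Shapiro-Wilk [{cond}]: W={g.statistic:.2f}, p={g.p:.3f} ({verdict})"
            )
        lines.append(
            "phase medians (of per-child medians): "
            + ", ".join(f"{k}={v:.0f}" for k, v in self.phase_medians.items())
        )
        if self.condition_medians:
            lines.append(
                "condition medians: "
                + ", ".join(f"{k}={v:.0f}" for k, v in self.condition_medians.items())
            )
        lines.append(
            f"Friedman: chi2({self.friedman_df})={self.friedman_chi2:.1f}, "
            f"p={self.friedman_p:.3g}"
        )
        lines.append(
            f"post hocs (Wilcoxon signed-rank, corrected alpha={self.corrected_alpha:.4f}):"
        )
        for c in self.comparisons:
            star = "*" if c.significant else " "
            lines.append(
                f"  {c.phase_a} vs {c.phase_b}: W={c.W:g}, Z={c.Z:.2f}, "
                f"p={c.p:.3g}, r={c.r:.3f} {star}"
            )
        s, t, p = self.binomial
        lines.append(f"children increasing under the game: {s}/{t} (binomial p={p:.3g})")
        return "\n".join(lines)

    def plot_phases(self, ax=None):
        """Box plot of per-child phase medians by phase (summary figure)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        labels = list(self.phase_medians)
        data = [self.summaries[f"median_{lab}"] for lab in labels]
        ax.boxplot(data, tick_labels=labels)
        ax.set_ylabel("median daily steps per child")
        ax.set_xlabel("phase")
        return ax


def run_analysis(records, design: StudyDesign | None = None, *,
                 alpha: float = 0.05, drop_nonwear: bool = True,
                 method: str = "auto") -> PhaseReversalResults:
    """One-call convenience wrapper: build the model and fit it."""
    return PhaseReversalModel(
        records, design, alpha=alpha, drop_nonwear=drop_nonwear
    ).fit(method=method)
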