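# Methods

## Scope and data model

`stepgoals` models a class-level physical-activity intervention evaluated in
an ABAB reversal design. The unit of raw data is one child's total step count
on one school day (long CSV: `child_id,day,steps`); days are consecutive
1-based school-day indices with no calendar structure (weekends and holidays
do not exist in the data model). The default design is four 10-day phases —
baseline1 (1–10), game1 (11–20), baseline2 (21–30), game2 (31–40) — but any
contiguous, non-overlapping phase plan covering days 1..D is accepted, with
each phase labelled and assigned to the `baseline` or `game` condition.

Missing data policy: medians are computed over the children present (i.e.
recorded) on a day and over the days a child is present in a phase; a day
with zero observations is an error, never imputed. A child-day of exactly 0
steps is read as the device not being worn and is dropped by the analysis
model by default (`drop_nonwear=True`); the schedule/goals path does not
filter, so goal recomputation from a cohort file reproduces the simulator's
in-loop outcomes exactly.

## The percentile schedule

On each game day d the goal is the `percentile` (default 0.60) of the class's
daily medians over the `window_size` (default 10) immediately preceding study
days — *strictly* the preceding calendar-of-study days, so the window crosses
phase boundaries: with the default design, day 31's window is the baseline2
days 21–30. Attainment is inclusive: met ⇔ daily median ≥ goal. The
"goal falls after failure / rises after success" behaviour is emergent from
the moving window; there is no separate adjustment rule.

Two percentile conventions are provided because the classical
behaviour-analysis literature uses order statistics while general-purpose
software interpolates:

- `linear` (default): index h = 1 + p(n−1) into the sorted window, linear
  interpolation between adjacent order statistics (identical to
  `numpy.quantile`'s default);
- `nearest_rank`: the ⌈p·n⌉-th order statistic (k = 6 for p = 0.6, n = 10).

For exchangeable continuous daily medians the nearest-rank rule has a
closed-form attainment probability P(met) = (n+1−k)/(n+1) = 5/11; the linear
rule's goal lies between the 6th and 7th order statistics, so its attainment
rate is bracketed by 4/11 and 5/11. Both facts are verified by long-run
simulation in the test suite (100,000 and 30,000 days respectively, ±0.01).

Episode release: an episode is shown on game day d iff the *most recent
preceding game day* met its goal. Keying off the most recent game day (rather
than strictly d−1) lets the first day of a resumed game phase present the
episode earned on the last day of the previous game phase; the first game day
of the whole study releases nothing.

## Statistical chain

All phase contrasts are built on the per-child median daily steps within each
phase (n pairs, one per child) — the most robust paired unit available from
daily totals. Condition-level quantities (normality gate, condition medians,
binomial test) pool each child's days across both phases of a condition.

1. **Shapiro–Wilk gate** per condition on the per-child condition medians
   (scipy implementation; `normal = p ≥ 0.05`). A constant vector is an
   error. The pipeline is nonparametric regardless; the gate documents
   whether that choice was forced.
2. **Friedman omnibus** over the n×k matrix of per-child phase medians:
   within-row mid-ranks, χ² = 12/(nk(k+1))·ΣR²ⱼ − 3n(k+1), divided by the
   tie-correction factor 1 − Σ(t³−t)/(nk(k²−1)); df = k−1, upper-tail
   chi-square p. Implemented in-package (the contract covers k = 2, which
   scipy's routine rejects); scipy's `friedmanchisquare` serves as an
   independent cross-check in the tests. Missing cells are an error.
3. **Wilcoxon matched-pairs signed-rank post hocs**, all k(k−1)/2 pairs, each
   at the Bonferroni-corrected α = family α / m (reported to 4 decimals;
   0.05/6 = 0.0083). Convention: differences d = y − x; zero differences
   dropped (reducing effective n); mid-ranks on |d|; **W = Σ sign(d)·rank**
   (range ±n(n+1)/2); Z = W/σ with σ² = n(n+1)(2n+1)/6 − Σ(t³−t)/12 and no
   continuity correction; two-sided p from the normal tail, or from exact
   enumeration of all 2ⁿ sign patterns when effective n ≤ 12. Effect size
   r = Z/√(2n), N counting observations in both conditions. This is the
   unique convention under which published signed-rank sums of 425, 399, 343
   and 335 over 29 pairs yield effect sizes 0.603, 0.566, 0.487 and 0.476;
   the package verifies all four reconstructions in its tests.
4. **Binomial test**: success = child's game-condition step sum strictly
   exceeds their baseline sum; exact ties are excluded from the trials (a tie
   is evidence for neither direction); exact two-sided p at p₀ = 0.5 by the
   minimum-likelihood method (scipy `binomtest`).

Only the post-hoc family is multiplicity-corrected; the omnibus and binomial
tests are reported at their nominal levels.

### Numerical notes

- The uncorrected normal approximation to the exact signed-rank p has a
  worst-case two-sided error of ~0.05 at n = 10 (exhaustive enumeration),
  attained near the centre of the null distribution; in the decision-relevant
  tail (exact p ≤ 0.05) the worst case is 0.0035. The exact route is
  therefore the default for effective n ≤ 12; a continuity correction would
  tighten the centre but break the convention that reproduces the published
  statistics, so none is applied.
- Outcome CSVs store floats via `repr` and are re-read as strings to
  guarantee bit-exact round trips; absent goal/met fields are empty strings.

## Synthetic classroom

No raw per-child data accompany published studies of this design, so the
generator emulates the study conditions rather than any particular dataset.
Child i on day d emits

    steps = max(0, round(mu_i + game_d·(delta + gamma·miss) + eps_id)),

mu_i ~ N(mu_mean, mu_sd) once per child, eps_id ~ N(0, eps_sd) fresh daily,
`miss` the indicator that the most recent preceding game day's goal was
missed. The loop is closed: each day's class median feeds the moving-window
goal, and the met/missed state feeds episode release and (via gamma)
next-game-day effort. Defaults — 29 children, 40 days, mu_mean 3300, mu_sd
600, eps_sd 500, delta 800, gamma 0 — target the magnitudes of the study
this package models (baseline condition median ≈ 3300 steps/day, game uplift
≈ 800); mu_sd and eps_sd are chosen as a realistic split of between- versus
within-child variation at that scale, not fitted to any dataset. gamma
defaults to 0 so the no-effect null stays analytically checkable (attainment
5/11); positive gamma is the mechanism that pushes attainment toward the
~80% observed in real classrooms, since a miss recruits extra class-wide
effort and the window rule then lowers the next goal. Feedback is class-wide,
not per-child, because goals and episodes are class-level contingencies.

What the generator does **not** model: minute-level accelerometry, wear-time
variation, weekday structure, skewed or heavy-tailed step distributions,
child-specific responsiveness to the game. Passing tests therefore show the
pipeline is correct and well-calibrated under an additive-Gaussian classroom,
not that any real classroom follows that model.

`recover_effect` closes the validation loop: per grid value of delta it
simulates cohorts, runs the full analysis, and reports (a) power = fraction
of replicates with all four adjacent/reversal contrasts significant at the
corrected α and (b) the mean recovered uplift, estimated as the median across
children of (game-condition median − baseline-condition median), which is
unbiased for delta under the symmetric model.

## Problem sizes and checks performed

The suite verifies, among others: the four effect-size reconstructions (to 3
decimals); Bonferroni 0.05/6 = 0.0083; nearest-rank null attainment over
100,010 simulated days within ±0.01 of 5/11; pipeline power ≥ 0.9 and mean
recovered uplift within ±50 of delta = 800 over 200 replicates, with the
all-four-contrasts rate at delta = 0 bounded by 0.035 over 200 replicates;
omnibus type-I rate over 400 null cohorts ≤ 0.08; Shapiro type-I rate over
1,000 draws in 0.05 ± 0.02; and cross-checks of every fast path against an
independent oracle (scipy Wilcoxon/Friedman, an R-derived Shapiro constant,
brute-force order statistics, exhaustive sign-pattern enumeration). These
replicate counts are the package's chosen defaults; larger runs only sharpen
the same comparisons.

## Known limitations

- The behavioural response model (additive delta, class-wide gamma) is a
  transparent stand-in; no mechanistic fidelity to real classrooms is
  claimed.
- Exact Wilcoxon enumeration is O(2ⁿ) and capped at n = 12; beyond that the
  tie-corrected normal approximation is used.
- The binomial tie-exclusion rule and the zero-step non-wear filter are
  documented defaults for situations real studies rarely specify; both are
  configurable at the API level where they matter.
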