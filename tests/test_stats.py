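"""Nonparametric chain: Wilcoxon convention, Friedman, gates, binomial."""

import itertools
import json
import math

import numpy as np
import pytest
from scipy import stats as sps

from stepgoals import (
    PhaseReversalModel,
    SimParams,
    all_increase_binomial,
    bonferroni_alpha,
    child_phase_summaries,
    effect_size_r,
    friedman_test,
    run_analysis,
    shapiro_gate,
    signed_rank_z,
    simulate_cohort,
    wilcoxon_signed_rank,
)

# Reported (signed-rank sum, effect size) pairs for n=29 matched pairs:
# the signed-rank-sum convention with Z = W/sqrt(n(n+1)(2n+1)/6) and
# r = Z/sqrt(2n) must reproduce r to 3 decimals.
REPORTED_W_R = [(425, 0.603), (399, 0.566), (343, 0.487), (335, 0.476)]


class TestWilcoxon:
    def test_identical_samples_undefined(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])

    def test_small_sample_exact_enumeration(self):
        # differences {+1,+1,+1,+2} after dropping the zero pair:
        # W = 2+2+2+4 = 10, the maximum; exact two-sided p = 2/16
        x = [0.0, 0.0, 0.0, 0.0, 5.0]
        y = [1.0, 1.0, 1.0, 2.0, 5.0]
        res = wilcoxon_signed_rank(x, y)
        assert res.method == "exact"
        assert res.n_pairs == 4
        assert res.W == 10
        assert res.p == pytest.approx(0.125)

    @pytest.mark.parametrize("w, r_expected", REPORTED_W_R)
    def test_signed_rank_effect_size_convention(self, w, r_expected):
        z = signed_rank_z(w, 29)
        assert z == pytest.approx(w / math.sqrt(8555))
        assert round(effect_size_r(z, 29), 3) == r_expected

    def test_symmetry_swap_negates_w_and_z(self, rng):
        x = rng.normal(size=29)
        y = rng.normal(loc=0.5, size=29)
        fwd = wilcoxon_signed_rank(x, y, method="normal")
        rev = wilcoxon_signed_rank(y, x, method="normal")
        assert rev.W == -fwd.W
        assert rev.Z == pytest.approx(-fwd.Z)
        assert rev.p == pytest.approx(fwd.p)
        assert abs(effect_size_r(rev.Z, rev.n_pairs)) == pytest.approx(
            abs(effect_size_r(fwd.Z, fwd.n_pairs))
        )

    def test_normal_p_matches_scipy(self, rng):
        """Independent oracle: scipy's approximate signed-rank p (no
        continuity correction) on tie-free continuous data."""
        for _ in range(10):
            x = rng.normal(size=25)
            y = x + rng.normal(loc=0.3, size=25)
            res = wilcoxon_signed_rank(x, y, method="normal")
            ref = sps.wilcoxon(y, x, correction=False, method="approx")
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exact_p_matches_scipy(self, rng):
        for _ in range(10):
            x = rng.normal(size=10)
            y = x + rng.normal(loc=0.5, size=10)
            res = wilcoxon_signed_rank(x, y, method="exact")
            ref = sps.wilcoxon(y, x, method="exact")
            assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_w_bounded_by_rank_sum(self, rng):
        for n in (5, 12, 29):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = wilcoxon_signed_rank(x, y, method="normal")
            assert abs(res.W) <= res.n_pairs * (res.n_pairs + 1) / 2


class TestFriedman:
    def test_perfect_ordering_k4(self):
        # every row strictly increasing over k=4 phases: chi2 = 3n
        n = 29
        m = np.arange(4)[None, :] + np.arange(n)[:, None] * 10
        chi2, df, p = friedman_test(m)
        assert chi2 == pytest.approx(3 * n)
        assert df == 3

    def test_perfect_ordering_k3(self):
        n = 5
        m = np.arange(3)[None, :] + np.arange(n)[:, None]
        chi2, df, _ = friedman_test(m)
        assert chi2 == pytest.approx(2 * n)
        assert df == 2

    def test_rank_invariance_under_monotone_transform(self, rng):
        m = rng.uniform(1, 100, size=(12, 4))
        chi2_raw, _, p_raw = friedman_test(m)
        chi2_t, _, p_t = friedman_test(np.exp(m / 25.0))
        assert chi2_t == pytest.approx(chi2_raw)
        assert p_t == pytest.approx(p_raw)

    def test_matches_scipy_without_ties(self, rng):
        m = rng.normal(size=(15, 4))
        chi2, _, p = friedman_test(m)
        ref = sps.friedmanchisquare(*m.T)
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_matches_scipy_with_ties(self, rng):
        m = rng.integers(0, 4, size=(20, 3)).astype(float)
        chi2, _, p = friedman_test(m)
        ref = sps.friedmanchisquare(*m.T)
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_upper_bound(self, rng):
        m = rng.normal(size=(29, 4))
        chi2, _, _ = friedman_test(m)
        assert chi2 <= 29 * 3 + 1e-9

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, 2.0], [np.nan, 3.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            friedman_test(m)


class TestShapiroGate:
    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            shapiro_gate([5.0] * 10)

    def test_uniform_grid_matches_reference(self):
        # frozen from an independent reference implementation (R shapiro.test)
        gate = shapiro_gate(list(range(1, 21)))
        assert gate.statistic == pytest.approx(0.9603751831, abs=1e-6)
        assert gate.p == pytest.approx(0.5513717, abs=1e-5)
        assert gate.normal

    def test_type_one_error_rate(self, rng):
        rejections = sum(
            not shapiro_gate(rng.normal(size=29)).normal for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07


class TestSmallPieces:
    @pytest.mark.parametrize(
        "alpha, m, expected",
        [(0.05, 6, 0.0083), (0.05, 1, 0.05), (0.01, 4, 0.0025)],
    )
    def test_bonferroni(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == expected

    def test_bonferroni_zero_comparisons(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)

    def test_effect_size_zero(self):
        assert effect_size_r(0.0, 29) == 0.0

    def test_binomial_all_success(self):
        import pandas as pd

        df = pd.DataFrame({"total_baseline": [100] * 29,
                           "total_game": [200] * 29})
        s, t, p = all_increase_binomial(df)
        assert (s, t) == (29, 29)
        assert p == pytest.approx(2 * 0.5**29)

    @pytest.mark.parametrize("succ, n, expected", [(5, 10, 1.0), (1, 1, 1.0)])
    def test_binomial_symmetric(self, succ, n, expected):
        import pandas as pd

        df = pd.DataFrame(
            {"total_baseline": [0] * n,
             "total_game": [1] * succ + [-1] * (n - succ)}
        )
        assert all_increase_binomial(df)[2] == pytest.approx(expected)

    def test_binomial_ties_excluded(self):
        import pandas as pd

        df = pd.DataFrame({"total_baseline": [10, 10, 10],
                           "total_game": [20, 10, 30]})
        s, t, _ = all_increase_binomial(df)
        assert (s, t) == (2, 2)


class TestRunAnalysis:
    def test_report_medians_match_brute_force(self, design, small_cohort):
        records, _ = small_cohort
        results = run_analysis(records, design)
        summaries = child_phase_summaries(records, design)
        for label, value in results.phase_medians.items():
            assert value == pytest.approx(
                float(np.median(summaries[f"median_{label}"]))
            )

    def test_all_pairwise_comparisons_present(self, design, small_cohort):
        records, _ = small_cohort
        results = run_analysis(records, design)
        assert len(results.comparisons) == 6
        pairs = {frozenset((c.phase_a, c.phase_b)) for c in results.comparisons}
        assert pairs == {
            frozenset(p) for p in itertools.combinations(design.labels, 2)
        }
        assert results.corrected_alpha == 0.0083
        for c in results.comparisons:
            assert c.significant == (c.p < 0.0083)

    def test_report_json_round_trip(self, design, small_cohort, tmp_path):
        records, _ = small_cohort
        results = run_analysis(records, design)
        path = tmp_path / "report.json"
        results.to_json(path)
        parsed = json.loads(path.read_text())
        assert json.loads(json.dumps(parsed)) == parsed == results.to_dict()

    def test_model_results_roundtrip_from_csv(self, design, small_cohort, tmp_path):
        from stepgoals import write_records

        records, _ = small_cohort
        write_records(records, tmp_path / "cohort.csv")
        model = PhaseReversalModel.from_csv(tmp_path / "cohort.csv", design)
        direct = PhaseReversalModel(records, design)
        assert model.fit().to_dict() == direct.fit().to_dict()

    def test_summary_mentions_key_statistics(self, design, small_cohort):
        records, _ = small_cohort
        text = run_analysis(records, design).summary()
        assert "Friedman" in text and "Shapiro-Wilk" in text
        assert "alpha=0.0083" in text
        assert "binomial" in text

    def test_null_omnibus_type_one_error(self):
        """No-effect cohorts should trip the omnibus at roughly the nominal
        5% rate."""
        seeds = np.random.default_rng(77).integers(0, 2**31 - 1, size=400)
        hits = 0
        for s in seeds:
            records, _ = simulate_cohort(SimParams(delta=0.0, seed=int(s)))
            results = run_analysis(records, method="normal")
            hits += results.friedman_p < 0.05
        assert hits / len(seeds) <= 0.08
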