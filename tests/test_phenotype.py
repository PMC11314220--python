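"""Replicate processing, outlier screening and dispersion statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tocopls.phenotype import (
    aggregate_replicates,
    cohort_phenotype,
    covariate_screen,
    cv_from_summary,
    forkman_cv_test,
    grubbs_critical,
    grubbs_test,
    paired_meal_tests,
    pearson_ci,
    pearson_ci_from_r,
    percent_cv,
)


class TestGrubbs:
    def test_gross_outlier_flagged(self):
        values = np.array([10, 10.2, 9.8, 10.1, 9.9, 30.0])
        idx, result = grubbs_test(values)
        assert idx == 5
        assert result.statistic == pytest.approx(2.041, abs=2e-3)
        assert grubbs_critical(6, 0.05) == pytest.approx(1.887, abs=2e-3)

    def test_constant_data_never_flag(self):
        idx, result = grubbs_test(np.full(6, 7.3))
        assert idx is None
        assert "zero_variance" in result.flags

    def test_tight_data_not_flagged(self):
        idx, result = grubbs_test(np.array([10, 10.2, 9.8, 10.1, 9.9, 10.3]))
        assert idx is None
        assert result.statistic == pytest.approx(1.336, abs=2e-3)

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            grubbs_test(np.array([1.0, 2.0]))

    def test_detection_probability_grows_with_offset(self, rng):
        hits = []
        for offset in (1.0, 5.0, 50.0):
            found = 0
            for _ in range(100):
                x = rng.normal(100, 1, size=6)
                x[0] += offset
                idx, _ = grubbs_test(x)
                found += idx == 0
            hits.append(found / 100)
        assert hits[0] < hits[1] <= hits[2] == 1.0


class TestAggregateReplicates:
    def test_symmetric_mean(self):
        agg = aggregate_replicates(np.array([100, 110, 120, 100, 110, 120.0]))
        assert agg.mean == pytest.approx(110.0)
        assert agg.n_used == 6

    def test_outlier_removed_before_averaging(self):
        agg = aggregate_replicates(np.array([10, 10.2, 9.8, 10.1, 9.9, 30.0]))
        assert agg.outlier_index == 5
        assert agg.n_used == 5
        assert agg.mean == pytest.approx(10.0)

    def test_single_pair(self):
        agg = aggregate_replicates(np.array([90.0, 110.0]))
        assert agg.mean == pytest.approx(100.0)

    def test_cohort_table(self):
        table = pd.DataFrame(
            {
                "participant_id": ["a"] * 3 + ["b"] * 2,
                "meal": ["control"] * 5,
                "time": ["fasting", "8h", "fasting", "fasting", "8h"],
                "adipose_atoc": [100.0, 110.0, 120.0, 90.0, 110.0],
            }
        )
        pheno = cohort_phenotype(table)
        assert pheno.loc["a", "atoc"] == pytest.approx(110.0)
        assert pheno.loc["b", "atoc"] == pytest.approx(100.0)


class TestPairedMealTests:
    def _table(self, post_shift, jitter, rng, n=12):
        rows = []
        for i in range(n):
            base = 100 + rng.normal(0, 10)
            for meal in ("control", "alpha_toc", "tomato"):
                rows.append({"participant_id": f"p{i}", "meal": meal,
                             "time": "fasting",
                             "adipose_atoc": base + jitter * rng.normal()})
                rows.append({"participant_id": f"p{i}", "meal": meal,
                             "time": "8h",
                             "adipose_atoc": base + post_shift
                             + jitter * rng.normal()})
        return pd.DataFrame(rows)

    def test_identical_baseline_and_post(self, rng):
        results = paired_meal_tests(self._table(0.0, 0.0, rng))
        for meal in ("control", "alpha_toc", "tomato"):
            r = results[f"{meal}:fasting_vs_8h"]
            assert r.statistic == 0.0
            assert r.p == 1.0

    def test_constant_shift_detected(self, rng):
        results = paired_meal_tests(self._table(5.0, 0.05, rng))
        assert results["control:fasting_vs_8h"].p < 0.01


class TestCV:
    @pytest.mark.parametrize(
        "mean,sd,expected",
        [
            (409.8, 206.7, 50.4),
            (82.9, 55.9, 67.4),
            (123.1, 69.5, 56.5),
            (281.0, 152.0, 54.1),
        ],
    )
    def test_summary_pairs(self, mean, sd, expected):
        assert cv_from_summary(mean, sd) == pytest.approx(expected, abs=0.05)

    def test_constant_vector_zero(self):
        assert percent_cv(np.full(10, 4.2)) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_mean_error(self):
        with pytest.raises(ValueError):
            percent_cv(np.array([-1.0, 1.0]))

    @given(st.floats(0.1, 100.0), st.integers(0, 2**31 - 1))
    def test_scale_invariance(self, c, seed):
        x = np.random.default_rng(seed).uniform(1, 10, size=12)
        assert percent_cv(c * x) == pytest.approx(percent_cv(x), rel=1e-9)


class TestForkman:
    def test_identical_samples(self):
        x = np.array([10, 12, 9, 11, 10.5, 8.7])
        r = forkman_cv_test(x, x)
        assert r.statistic == pytest.approx(1.0)
        assert r.p == pytest.approx(1.0)

    def test_large_cv_gap_detected(self, rng):
        """61% vs 25% CV at n = 42: essentially always rejected."""
        reject = 0
        for _ in range(50):
            x = np.abs(rng.normal(100, 61, 42))
            y = rng.normal(100, 25, 42)
            reject += forkman_cv_test(x, y).p < 0.05
        assert reject >= 49

    def test_nonpositive_mean_error(self):
        with pytest.raises(ValueError):
            forkman_cv_test(np.array([-5, 1, 2.0]), np.array([1, 2, 3.0]))


class TestPearsonCI:
    def test_printed_interval_r036(self):
        ci = pearson_ci_from_r(0.36, 42)
        assert ci.lower == pytest.approx(0.06, abs=5e-3)
        assert ci.upper == pytest.approx(0.60, abs=5e-3)
        assert ci.test.p == pytest.approx(0.02, abs=5e-3)

    def test_printed_interval_r024(self):
        ci = pearson_ci_from_r(0.24, 42)
        assert ci.lower == pytest.approx(-0.07, abs=5e-3)
        assert ci.upper == pytest.approx(0.51, abs=5e-3)

    def test_perfect_correlation_degenerate(self):
        x = np.arange(10.0)
        ci = pearson_ci(x, x)
        assert ci.r == pytest.approx(1.0)
        assert "degenerate" in ci.test.flags

    def test_bounds_bracket_r_and_shrink_with_n(self, rng):
        for n in (10, 40, 160):
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            ci = pearson_ci(x, y)
            assert ci.lower < ci.r < ci.upper
        wide = pearson_ci_from_r(0.3, 10)
        narrow = pearson_ci_from_r(0.3, 160)
        assert (narrow.upper - narrow.lower) < (wide.upper - wide.lower)


class TestCovariateScreen:
    def test_phenotype_copy_kept_noise_mostly_dropped(self, rng):
        pheno = pd.Series(rng.normal(100, 30, 42),
                          index=[f"p{i}" for i in range(42)])
        cov = pd.DataFrame(
            {
                "copy": pheno.to_numpy(),
                "noise1": rng.normal(size=42),
                "noise2": rng.normal(size=42),
            },
            index=pheno.index,
        )
        kept, table = covariate_screen(pheno, cov)
        assert "copy" in kept
        assert table.loc["copy", "kept"]

    def test_correlated_covariate_kept_at_printed_strength(self, rng):
        """r around 0.5 at n=42 has a CI clear of zero."""
        z = rng.normal(size=42)
        pheno = pd.Series(100 + 30 * z, index=[f"p{i}" for i in range(42)])
        cov = pd.DataFrame(
            {"tc": 1.6 + 0.6 * (0.7 * z + 0.3 * rng.normal(size=42))},
            index=pheno.index,
        )
        kept, _ = covariate_screen(pheno, cov)
        assert kept == ["tc"]
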