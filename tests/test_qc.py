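"""Genotype QC: call-rate filter, HWE test, LD measures, tag selection, dedup."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tocopls.qc import (
    call_rate_filter,
    dedup_perfect_pairs,
    dosage_r2,
    hwe_test,
    run_qc,
    tag_snp_selection,
)

from conftest import make_matrix


def _hwe_vector(n0, n1, n2):
    return [0.0] * n0 + [1.0] * n1 + [2.0] * n2


class TestCallRateFilter:
    @pytest.mark.parametrize(
        "n_missing,kept",
        [(0, True), (2, True), (3, False)],  # 40/42 = 0.952 passes, 39/42 fails
    )
    def test_threshold_at_42_participants(self, n_missing, kept):
        col = np.array([0.0, 1.0] * 21)
        col[:n_missing] = np.nan
        g = make_matrix({"snp": col, "anchor": np.array([0.0, 1.0] * 21)})
        filtered, excluded = call_rate_filter(g, 0.95)
        assert ("snp" in filtered.snp_ids) is kept
        assert ("snp" in excluded) is (not kept)

    def test_empty_matrix_errors(self):
        g = make_matrix({"snp": [0, 1, 2]})
        with pytest.raises(ValueError):
            call_rate_filter(g.subset([]), 0.95)


class TestHWE:
    @pytest.mark.parametrize(
        "counts,chi2,p",
        [
            ((25, 50, 25), 0.0, 1.0),          # exact HWE proportions
            ((30, 10, 2), 0.857, 0.3545),      # expected (29.17, 11.67, 1.17)
            ((20, 2, 20), 34.381, 4.6e-9),     # strong heterozygote deficit
        ],
    )
    def test_hand_computed_examples(self, counts, chi2, p):
        result = hwe_test(*counts)
        assert result.statistic == pytest.approx(chi2, abs=2e-3)
        assert result.p == pytest.approx(p, rel=0.01, abs=1e-9)

    def test_monomorphic_flagged_not_excludable(self):
        result = hwe_test(42, 0, 0)
        assert result.statistic == 0.0
        assert result.p == 1.0
        assert "monomorphic" in result.flags

    def test_matches_first_principles_chisquare(self, rng):
        """Oracle equivalence against scipy's generic chi-square on random triples."""
        for _ in range(200):
            counts = rng.integers(0, 30, size=3)
            n = counts.sum()
            if n == 0:
                continue
            p_hat = (counts[1] + 2 * counts[2]) / (2 * n)
            if p_hat in (0.0, 1.0):
                continue
            expected = n * np.array(
                [(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat**2]
            )
            oracle = stats.chisquare(counts, expected, ddof=1)
            ours = hwe_test(*counts)
            assert ours.statistic == pytest.approx(oracle.statistic, rel=1e-12)
            assert ours.p == pytest.approx(oracle.pvalue, rel=1e-9, abs=1e-12)


class TestDosageR2:
    def test_self_correlation_is_one(self):
        v = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        assert dosage_r2(v, v) == pytest.approx(1.0)

    def test_allele_flip_invariance(self):
        v = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        assert dosage_r2(v, 2 - v) == pytest.approx(1.0)

    def test_six_pair_fixture(self):
        # direct Pearson computation: cov 0.6, var 0.8 and 2/3 -> r2 = 0.675
        g1 = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        g2 = np.array([0, 1, 1, 2, 2, 2], dtype=float)
        assert dosage_r2(g1, g2) == pytest.approx(0.675, abs=1e-12)

    def test_zero_variance_reports_missing(self):
        assert np.isnan(dosage_r2(np.ones(6), np.array([0, 1, 2, 0, 1, 2.0])))

    def test_pairwise_complete_handling(self):
        g1 = np.array([0, 0, 1, 1, 2, 2, np.nan])
        g2 = np.array([0, 0, 1, 1, 2, 2, 0.0])
        assert dosage_r2(g1, g2) == pytest.approx(1.0)


class TestTagSelection:
    def test_independent_snps_all_tags(self, rng):
        cols = {f"s{i}": rng.binomial(2, 0.4, 60).astype(float) for i in range(5)}
        g = make_matrix(cols, genes={k: "G1" for k in cols})
        tags, bins = tag_snp_selection(g, 0.80)
        assert tags == list(cols)

    def test_mutually_perfect_trio_one_tag(self):
        base = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 1], dtype=float)
        g = make_matrix(
            {"a": base, "b": base, "c": 2 - base},
            genes={"a": "G1", "b": "G1", "c": "G1"},
        )
        tags, bins = tag_snp_selection(g, 0.80)
        assert tags == ["a"]
        assert sorted(bins["a"]) == ["a", "b", "c"]

    def test_hub_and_singletons(self, rng):
        """A linked to B and C only; D and E independent -> tags {A, D, E}."""
        base = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 1], dtype=float)
        d = rng.binomial(2, 0.5, 10).astype(float)
        e = rng.binomial(2, 0.5, 10).astype(float)
        # guard the fixture's independence assumptions
        assert dosage_r2(base, d) < 0.8 and dosage_r2(base, e) < 0.8
        assert np.isnan(dosage_r2(d, e)) or dosage_r2(d, e) < 0.8
        g = make_matrix(
            {"A": base, "B": base, "C": 2 - base, "D": d, "E": e},
            genes={s: "G1" for s in "ABCDE"},
        )
        tags, _ = tag_snp_selection(g, 0.80)
        assert tags == ["A", "D", "E"]


class TestDedupPerfectPairs:
    def test_no_pairs_unchanged(self, rng):
        cols = {f"s{i}": rng.binomial(2, 0.4, 50).astype(float) for i in range(4)}
        g = make_matrix(cols)
        out, excluded = dedup_perfect_pairs(g, seed=1)
        assert excluded == []
        assert out.equals(g)

    def test_one_pair_single_survivor(self):
        base = np.array([0, 1, 2, 0, 1, 2, 1, 1], dtype=float)
        g = make_matrix({"x": base, "y": base.copy(), "z": base[::-1]})
        out, excluded = dedup_perfect_pairs(g, seed=3)
        assert len(excluded) == 1
        assert excluded[0] in {"x", "y"}

    def test_seeded_determinism(self):
        base = np.array([0, 1, 2, 0, 1, 2, 1, 1], dtype=float)
        g = make_matrix({"x": base, "y": base.copy()})
        first = dedup_perfect_pairs(g, seed=11)[1]
        second = dedup_perfect_pairs(g, seed=11)[1]
        assert first == second


class TestRunQC:
    def _clean_panel(self, rng, n_snps=4):
        cols = {}
        for i in range(n_snps):
            cols[f"clean{i}"] = rng.permutation(
                _hwe_vector(10, 22, 10)
            )
        return cols

    def test_clean_panel_zero_exclusions(self, rng):
        cols = self._clean_panel(rng)
        g = make_matrix(cols, genes={k: "G1" for k in cols})
        out, report = run_qc(g)
        assert out.snp_ids == list(cols)
        assert all(s.n_excluded == 0 for s in report.stages)

    def test_planted_violations_each_caught(self, rng):
        cols = self._clean_panel(rng)
        low_call = np.array(_hwe_vector(10, 22, 10))
        low_call[:5] = np.nan                          # call rate 37/42 < 0.95
        cols["low_call"] = low_call
        cols["hwe_bad"] = np.array(_hwe_vector(20, 2, 20))
        cols["dup"] = cols["clean0"].copy()            # perfect duplicate
        genes = {k: "G1" for k in cols}
        genes["dup"] = "G2"                            # different gene: passes tagging
        g = make_matrix(cols, genes=genes)
        out, report = run_qc(g, seed=5)
        reasons = {
            snp: reason
            for stage in report.stages
            for snp, reason in stage.excluded.items()
        }
        assert reasons["low_call"] == "call_rate"
        assert reasons["hwe_bad"] == "hwe"
        assert len(reasons) == 3
        assert list(reasons.values()).count("perfect_duplicate") == 1
        assert out.n_snps == g.n_snps - 3

    def test_report_chains_and_is_idempotent(self, rng):
        cols = self._clean_panel(rng)
        cols["hwe_bad"] = np.array(_hwe_vector(20, 2, 20))
        g = make_matrix(cols, genes={k: "G1" for k in cols})
        out, report = run_qc(g, seed=2)
        report.validate_chain()
        frame = report.to_frame()
        assert (frame["n_in"] - frame["n_excluded"] == frame["n_out"]).all()
        again, report2 = run_qc(out, seed=2)
        assert again.equals(out)
        assert all(s.n_excluded == 0 for s in report2.stages)

    def test_column_order_preserved(self, rng):
        cols = self._clean_panel(rng, n_snps=6)
        g = make_matrix(cols, genes={k: "G1" for k in cols})
        out, _ = run_qc(g)
        assert out.snp_ids == [s for s in g.snp_ids if s in set(out.snp_ids)]
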