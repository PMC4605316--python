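"""Correlation, differential-expression and enrichment statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

import oracles
from rsrna import stats
from rsrna.datamodel import CountMatrix, SampleMeta
from rsrna.datasets import load_qpcr_panel


class TestPearson:
    def test_matches_plain_formula_and_scipy(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = stats.pearson_correlation(x, y)
            assert res.r == pytest.approx(oracles.pearson_formula(x, y), abs=1e-12)
            r_sp, p_sp = sp_stats.pearsonr(x, y)
            assert res.r == pytest.approx(r_sp, abs=1e-12)
            assert res.p_value == pytest.approx(p_sp, rel=1e-9)

    def test_identity_gives_r_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = stats.pearson_correlation(x, x)
        assert res.r == 1.0 and res.p_value == 0.0

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        assert stats.pearson_correlation(x, y).r == pytest.approx(
            stats.pearson_correlation(y, x).r
        )
        assert stats.pearson_correlation(2.5 * x + 7, y).r == pytest.approx(
            stats.pearson_correlation(x, y).r
        )
        assert stats.pearson_correlation(-x, y).r == pytest.approx(
            -stats.pearson_correlation(x, y).r
        )

    def test_noiseless_inverse_relation_is_minus_one(self):
        x = np.array([1.0, 4.0, 2.0, 9.0, 5.0])
        res = stats.pearson_correlation(x, 10.0 - 3.0 * x)
        assert res.r == -1.0 and res.p_value == 0.0

    def test_pairwise_complete_drops_missing(self):
        x = [31.20, 32.02, 29.52, 28.50]
        y = [24.48, 22.24, 26.22, np.nan]
        res = stats.pearson_correlation(x, y)
        assert res.n_used == 3
        assert round(res.r, 2) == -0.96

    def test_undefined_cases_raise(self):
        with pytest.raises(stats.UndefinedCorrelationError):
            stats.pearson_correlation([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(stats.UndefinedCorrelationError):
            stats.pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(stats.UndefinedCorrelationError):
            stats.pearson_correlation([1, 2, np.nan, np.nan], [1, 2, 3, 4])


class TestWelch:
    def test_identical_groups(self):
        assert stats.welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(5, 1, 20)
        _t, p = stats.welch_ttest(a, b)
        assert p < 1e-6

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            a = rng.normal(size=int(rng.integers(3, 15)))
            b = rng.normal(loc=rng.normal(), size=int(rng.integers(3, 15)))
            t, p = stats.welch_ttest(a, b)
            t0, p0 = oracles.welch_formula(list(a), list(b))
            assert t == pytest.approx(t0, abs=1e-10)
            assert p == pytest.approx(p0, abs=1e-10)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            stats.welch_ttest([1.0], [1.0, 2.0])


def _rpm_matrix(rows):
    samples = [
        SampleMeta("t1", "c1", "tumor"), SampleMeta("t2", "c1", "tumor"),
        SampleMeta("n1", "c1", "normal"), SampleMeta("n2", "c1", "normal"),
    ]
    seqs = sorted(rows)
    counts = pd.DataFrame(
        {s.sample_id: [1] * len(seqs) for s in samples},
        index=pd.Index(seqs, name="sequence"), dtype=np.int64,
    )
    rpm = pd.DataFrame(
        {s.sample_id: [rows[seq][i] for seq in seqs] for i, s in enumerate(samples)},
        index=pd.Index(seqs, name="sequence"), dtype=float,
    )
    return CountMatrix(counts, samples, rpm)


class TestFoldChange:
    def test_pseudocount_blocks_borderline_call(self):
        cm = _rpm_matrix({"AAA": [20, 20, 10, 10]})
        calls, summary = stats.fold_change_flags(cm, 2.0, 0.5)
        [call] = calls
        assert call.fold_change == pytest.approx(20.5 / 10.5)
        assert call.direction == "unchanged"
        assert not summary.loc["AAA", "de_flag"]

    def test_fourfold_is_called_up_in_tumor(self):
        cm = _rpm_matrix({"AAA": [40, 40, 10, 10]})
        calls, summary = stats.fold_change_flags(cm, 2.0, 0.5)
        assert calls[0].fold_change == pytest.approx(40.5 / 10.5)
        assert calls[0].direction == "up_in_tumor"
        assert bool(summary.loc["AAA", "de_flag"])

    def test_down_direction(self):
        cm = _rpm_matrix({"AAA": [10, 10, 40, 40]})
        calls, summary = stats.fold_change_flags(cm, 2.0, 0.5)
        assert calls[0].direction == "up_in_normal"
        assert summary.loc["AAA", "up_in_normal"] == 1

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(12)
        rows = {f"s{i}": rng.integers(0, 100, 4).tolist() for i in range(30)}
        cm = _rpm_matrix(rows)
        prev = None
        for fc_min in (1.5, 2.0, 3.0, 5.0):
            _c, summary = stats.fold_change_flags(cm, fc_min, 0.5)
            flagged = set(summary.index[summary["de_flag"]])
            if prev is not None:
                assert flagged <= prev
            prev = flagged


class TestAnticorrelationScreen:
    def test_threshold_semantics(self):
        cols = [f"s{i}" for i in range(10)]
        x = np.arange(10.0)
        rpm = pd.DataFrame([x], index=["srna1"], columns=cols)
        expr = pd.DataFrame(
            [20.0 - x, x * 0 + np.random.default_rng(3).normal(5, 0.1, 10)],
            index=["anti", "flat"], columns=cols,
        )
        out = stats.anticorrelation_screen(rpm, expr, [("srna1", "anti"), ("srna1", "flat")])
        by_gene = out.set_index("gene_id")
        assert bool(by_gene.loc["anti", "passed"])        # r = -1, p = 0
        assert not bool(by_gene.loc["flat", "passed"])

    def test_requires_shared_samples(self):
        rpm = pd.DataFrame([[1.0, 2.0]], index=["x"], columns=["s1", "s2"])
        expr = pd.DataFrame([[1.0]], index=["g"], columns=["zz"])
        with pytest.raises(ValueError, match="shared"):
            stats.anticorrelation_screen(rpm, expr, [("x", "g")])


class TestCtCorrelationTable:
    def test_panel_pairs_reproduced(self):
        """The shipped qPCR panel reproduces its reported anti-correlations
        (full-precision values frozen from direct recomputation)."""
        ct, pairs, _reported = load_qpcr_panel()
        table = stats.ct_correlation_table(ct, pairs).set_index(["srna_id", "gene_id"])
        frozen = {
            ("rsRNA-1336", "FOXO3"): -0.626280,
            ("rsRNA-3091", "EMP2"): -0.772638,
            ("rsRNA-3790", "TAF8"): -0.563774,
            ("rsRNA-5402", "ATM"): -0.964180,
            ("rsRNA-7906", "EMP2"): -0.908304,
            ("rsRNA-8294", "E2F8"): -0.959268,
            ("rsRNA-9338", "TERF1"): -0.976466,
            ("rsRNA-9345", "BRCA2"): -0.785145,
            ("rsRNA-3091", "TAF8"): -0.664077,
        }
        for pair, expected in frozen.items():
            assert table.loc[pair, "r"] == pytest.approx(expected, abs=1e-6)
        assert table.loc[("rsRNA-5402", "ATM"), "n_used"] == 3

    def test_insufficient_complete_pairs_reported_na(self):
        ct = pd.DataFrame(
            {"a": [1.0, 2.0], "b": [2.0, np.nan], "c": [np.nan, 3.0]},
            index=pd.Index(["r", "g"], name="entity"),
        )
        out = stats.ct_correlation_table(ct, [("r", "g")])
        assert math.isnan(out.loc[0, "r"])
        assert out.loc[0, "note"] != ""

    def test_column_permutation_invariance(self):
        ct, pairs, _ = load_qpcr_panel()
        shuffled = ct[ct.columns[::-1]]
        a = stats.ct_correlation_table(ct, pairs)["r"]
        b = stats.ct_correlation_table(shuffled, pairs)["r"]
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestHypergeometricEnrichment:
    def test_complete_overlap_matches_exact_sum(self):
        universe = [f"g{i}" for i in range(100)]
        cat = set(universe[:5])
        out = stats.hypergeometric_enrichment(cat, universe, {"c": cat})
        expected = oracles.hypergeom_upper_tail(5, 100, 5, 5)
        assert out.loc[0, "p_raw"] == pytest.approx(expected, rel=1e-9)

    def test_disjoint_category_is_not_significant(self):
        universe = [f"g{i}" for i in range(50)]
        out = stats.hypergeometric_enrichment(
            universe[:5], universe, {"c": universe[40:]}
        )
        # overlap 0: upper tail P(X >= 0) = 1
        assert out.loc[0, "overlap"] == 0
        assert out.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_single_category_bonferroni_identity(self):
        universe = [f"g{i}" for i in range(30)]
        out = stats.hypergeometric_enrichment(universe[:4], universe, {"c": universe[2:8]})
        assert out.loc[0, "p_bonferroni"] == pytest.approx(out.loc[0, "p_raw"])

    def test_matches_exact_sum_on_random_instances(self):
        rng = np.random.default_rng(19)
        for _ in range(100):
            n_u = int(rng.integers(10, 200))
            universe = [f"g{i}" for i in range(n_u)]
            targets = list(rng.choice(universe, size=int(rng.integers(1, n_u // 2 + 1)), replace=False))
            cat = list(rng.choice(universe, size=int(rng.integers(1, n_u)), replace=False))
            out = stats.hypergeometric_enrichment(targets, universe, {"c": cat})
            overlap = len(set(targets) & set(cat))
            expected = oracles.hypergeom_upper_tail(overlap, n_u, len(cat), len(targets))
            assert out.loc[0, "overlap"] == overlap
            assert out.loc[0, "p_raw"] == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            stats.hypergeometric_enrichment([], [], {"c": []})
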