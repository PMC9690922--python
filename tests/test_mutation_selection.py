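import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chlorocodon.codon_core import FOURFOLD_FAMILIES, GENETIC_CODE, CodonCountVector
from chlorocodon.mutation_selection import (
    CONTEXT_DATASETS,
    ContingencyTable,
    IndependenceTestResult,
    NeutralityPoint,
    bh_correct,
    build_context_tables,
    nc_deviation,
    neutrality_point,
    neutrality_regression,
    test_independence as run_independence_test,
)


class TestNcDeviation:
    def test_no_deviation(self):
        assert nc_deviation(50.0, 50.0) == (0.0, 0.0)

    def test_arithmetic(self):
        diff, ratio = nc_deviation(40.0, 50.0)
        assert diff == pytest.approx(10.0) and ratio == pytest.approx(0.2)

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            nc_deviation(40.0, 0.0)


class TestNeutralityPoint:
    def test_all_gc(self):
        pt = neutrality_point(CodonCountVector.from_dict({"GGG": 7}))
        assert (pt.P1, pt.P2, pt.P3, pt.P12) == (100.0, 100.0, 100.0, 100.0)

    def test_ata_excluded(self):
        pt = neutrality_point(CodonCountVector.from_dict({"ATA": 5, "GCG": 5}))
        assert (pt.P1, pt.P2, pt.P3) == (100.0, 100.0, 100.0)

    def test_hand_tally(self):
        pt = neutrality_point(CodonCountVector.from_dict({"TTT": 1, "GGC": 1}))
        assert (pt.P1, pt.P2, pt.P3, pt.P12) == (50.0, 50.0, 50.0, 50.0)

    def test_nothing_left_raises(self):
        with pytest.raises(ValueError):
            neutrality_point(CodonCountVector.from_dict({"ATG": 3, "ATA": 2}))


class TestNeutralityRegression:
    def test_exact_line(self):
        pts = [NeutralityPoint(f"g{i}", 2 * x + 1, 2 * x + 1, x) for i, x in enumerate((1.0, 2.0, 5.0, 9.0))]
        fit = neutrality_regression(pts)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(10, 40, size=10)
        y = 0.3 * x + 35 + rng.normal(0, 2, size=10)
        pts = [NeutralityPoint(f"g{i}", yi, yi, xi) for i, (xi, yi) in enumerate(zip(x, y))]
        fit = neutrality_regression(pts)
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.slope == pytest.approx(beta[0])
        assert fit.intercept == pytest.approx(beta[1])

    def test_zero_variance_in_p3_rejected(self):
        pts = [NeutralityPoint(f"g{i}", float(i), float(i), 30.0) for i in range(5)]
        with pytest.raises(ValueError):
            neutrality_regression(pts)

    def test_too_few_points_rejected(self):
        pts = [NeutralityPoint("a", 1, 1, 1), NeutralityPoint("b", 2, 2, 2)]
        with pytest.raises(ValueError):
            neutrality_regression(pts)


class TestBuildContextTables:
    def test_six_datasets_with_printed_rows(self):
        tables = {t.name: t for t in build_context_tables(CodonCountVector.from_dict({"CTA": 1}))}
        assert set(tables) == set(CONTEXT_DATASETS)
        assert list(tables["Ser4/Pro/Thr/Ala"].counts.index) == ["Ser4", "Pro", "Thr", "Ala"]

    def test_ctn_only_vector_zero_val_row(self):
        v = CodonCountVector.from_dict({"CTA": 3, "CTC": 2})
        tables = {t.name: t for t in build_context_tables(v)}
        assert tables["Leu4/Val"].counts.loc["Val"].sum() == 0
        assert tables["Leu4/Val"].counts.loc["Leu4"].sum() == 5

    def test_hand_placement(self):
        v = CodonCountVector.from_dict({"CTA": 2, "CCA": 1, "CGA": 3})
        tables = {t.name: t for t in build_context_tables(v)}
        assert list(tables["Leu4/Pro/Arg4"].counts["A"]) == [2, 1, 3]

    def test_composite_rows_pool_cell_wise(self):
        v = CodonCountVector.from_dict({"CTA": 2, "GTA": 5, "TCA": 1, "GCA": 4})
        tables = {t.name: t for t in build_context_tables(v)}
        combined = tables["Leu4+Val/Ser4+Pro+Thr+Ala/Arg4+Gly"].counts
        assert combined.loc["Leu4+Val", "A"] == 7
        assert combined.loc["Ser4+Pro+Thr+Ala", "A"] == 5

    def test_conservation_of_fourfold_counts(self):
        rng = np.random.default_rng(4)
        v = CodonCountVector.from_dict({c: int(rng.integers(0, 40)) for c in GENETIC_CODE})
        fourfold_total = sum(
            v[c] for fam in FOURFOLD_FAMILIES.values() for c in fam.codons
        )
        for table in build_context_tables(v):
            if table.name == "Leu4+Val/Ser4+Pro+Thr+Ala/Arg4+Gly":
                assert table.total() == fourfold_total


class TestIndependence:
    def test_perfectly_independent_table(self):
        t = ContingencyTable("toy", pd.DataFrame([[10, 10], [10, 10]], columns=["A", "C"]))
        res = run_independence_test(t, "pearson_chi2")
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_proportional_rows_give_zero_chi2(self):
        t = ContingencyTable("toy", pd.DataFrame([[2, 4, 6], [5, 10, 15]], columns=list("ACG")))
        assert run_independence_test(t, "pearson_chi2").statistic == pytest.approx(0.0)

    def test_fisher_2x2_closed_form(self):
        """Fully segregated 2x2 (5,0/0,5): two tables of the hypergeometric
        support reach probability <= observed, p = 2/C(10,5) = 1/126."""
        t = ContingencyTable("toy", pd.DataFrame([[5, 0], [0, 5]], columns=["A", "C"]))
        assert run_independence_test(t, "fisher_exact").p == pytest.approx(2 / 252)

    def test_fisher_2x2_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            arr = rng.integers(0, 10, size=(2, 2))
            if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
                continue
            t = ContingencyTable("toy", pd.DataFrame(arr, columns=["A", "C"]))
            ours = run_independence_test(t, "fisher_exact").p
            oracle = stats.fisher_exact(arr)[1]
            assert ours == pytest.approx(oracle, rel=1e-9)

    def test_enumeration_and_monte_carlo_agree(self):
        rng = np.random.default_rng(13)
        arr = rng.integers(1, 8, size=(3, 4))
        t = ContingencyTable("toy", pd.DataFrame(arr, columns=list("ACGT")))
        exact = run_independence_test(t, "fisher_exact", max_enumeration=10_000_000).p
        mc = run_independence_test(t, "fisher_exact", max_enumeration=0, mc_samples=40_000, seed=1).p
        assert mc == pytest.approx(exact, abs=0.02)

    def test_monte_carlo_is_seed_deterministic(self):
        arr = np.array([[8, 2, 5, 3], [1, 9, 2, 6]])
        t = ContingencyTable("toy", pd.DataFrame(arr, columns=list("ACGT")))
        p1 = run_independence_test(t, "fisher_exact", max_enumeration=0, mc_samples=5000, seed=7).p
        p2 = run_independence_test(t, "fisher_exact", max_enumeration=0, mc_samples=5000, seed=7).p
        assert p1 == p2

    def test_zero_rows_dropped_before_testing(self):
        t = ContingencyTable(
            "toy", pd.DataFrame([[5, 5], [0, 0], [4, 6]], columns=["A", "C"])
        )
        res = run_independence_test(t, "pearson_chi2")
        assert res.p > 0  # runs on the 2x2 sub-table

    def test_degenerate_table_rejected(self):
        t = ContingencyTable("toy", pd.DataFrame([[5, 5], [0, 0]], columns=["A", "C"]))
        with pytest.raises(ValueError, match="degenerate"):
            run_independence_test(t, "pearson_chi2")


class TestBHCorrection:
    @staticmethod
    def _results(ps):
        return [IndependenceTestResult(f"d{i}", "pearson_chi2", 0.0, p) for i, p in enumerate(ps)]

    def test_all_small_p_significant(self):
        out = bh_correct(self._results([0.001] * 6), fdr=0.05)
        assert all(r.p_bh_significant for r in out)

    def test_hand_step_up_no_rejections(self):
        """Step-up by hand for (0.01, 0.02, 0.04, 0.5, 0.6, 0.9) at FDR 0.05:
        every sorted p exceeds its threshold i*0.05/6, so nothing is
        rejected."""
        out = bh_correct(self._results([0.01, 0.02, 0.04, 0.5, 0.6, 0.9]), fdr=0.05)
        assert not any(r.p_bh_significant for r in out)

    def test_hand_step_up_rescue(self):
        """Step-up rescue: with (0.001, 0.013, 0.04, 0.5) at FDR 0.05 the
        largest passing index is i=2 (0.013 <= 2*0.05/4), so the first two
        are rejected even though 0.013 > 0.05/4."""
        out = bh_correct(self._results([0.001, 0.013, 0.04, 0.5]), fdr=0.05)
        assert [r.p_bh_significant for r in out] == [True, True, False, False]

    def test_invalid_fdr_rejected(self):
        with pytest.raises(ValueError):
            bh_correct(self._results([0.5]), fdr=1.5)
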