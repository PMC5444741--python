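import itertools

import numpy as np
import pytest
from statsmodels.stats.power import TTestIndPower

from reopure import (
    ExpressionMatrix,
    concordance_pvalue,
    concordance_score,
    correlate_with_ptec,
    differential_expression,
)


def brute_force_upper_tail(k: int, s: int) -> float:
    """P(X >= s) for X ~ Binomial(k, 0.5), by enumerating all 2^k outcomes."""
    hits = sum(1 for outcome in itertools.product([0, 1], repeat=k) if sum(outcome) >= s)
    return hits / 2**k


class TestCorrelateWithPtec:
    @pytest.fixture
    def ptec(self):
        return np.array([20.0, 45.0, 60.0, 75.0, 90.0])

    def test_perfect_monotone_agreement_and_inversion(self, ptec):
        m = ExpressionMatrix(
            ["track", "anti"],
            [f"s{i}" for i in range(5)],
            np.vstack([ptec, 100.0 - ptec]),
        )
        table = correlate_with_ptec(m, ptec)
        assert table.loc["track", "spearman_rho"] == pytest.approx(1.0)
        assert table.loc["track", "direction"] == "positive"
        assert table.loc["anti", "spearman_rho"] == pytest.approx(-1.0)
        assert table.loc["anti", "direction"] == "negative"

    def test_zero_variance_gene_excluded(self, ptec):
        m = ExpressionMatrix(
            ["flat", "ok"], [f"s{i}" for i in range(5)], np.vstack([np.full(5, 3.0), ptec])
        )
        table = correlate_with_ptec(m, ptec)
        assert "flat" not in table.index
        assert "ok" in table.index

    def test_fewer_than_three_samples_is_an_error(self):
        m = ExpressionMatrix(["g"], ["s1", "s2"], np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError, match="3 samples"):
            correlate_with_ptec(m, [50.0, 60.0])


class TestDifferentialExpression:
    def test_identical_groups_are_null(self, rng):
        values = rng.normal(6, 1, (10, 4))
        epi = ExpressionMatrix([f"g{i}" for i in range(10)], ["e1", "e2", "e3", "e4"], values)
        stro = ExpressionMatrix([f"g{i}" for i in range(10)], ["t1", "t2", "t3", "t4"], values)
        table = differential_expression(epi, stro)
        assert np.allclose(table["t_statistic"], 0.0)
        assert np.allclose(table["raw_p"], 1.0)

    def test_regulation_follows_sign_of_mean_difference(self):
        epi = ExpressionMatrix(
            ["g"], ["e1", "e2", "e3"], np.array([[10.0, 10.5, 9.5]])
        )
        stro = ExpressionMatrix(["g"], ["t1", "t2", "t3"], np.array([[2.0, 2.5, 1.5]]))
        table = differential_expression(epi, stro)
        assert table.loc["g", "regulation"] == "up"
        assert table.loc["g", "t_statistic"] > 0

    def test_disjoint_gene_sets_error(self):
        epi = ExpressionMatrix(["gA"], ["e1", "e2"], np.ones((1, 2)))
        stro = ExpressionMatrix(["gB"], ["t1", "t2"], np.ones((1, 2)))
        with pytest.raises(ValueError, match="share no genes"):
            differential_expression(epi, stro)

    def test_planted_shift_detection_beats_closed_form_power_bound(self, rng):
        """Planted-effect genes at FDR<0.1 at or above the noncentral-t power bound.

        The oracle is the closed-form two-sample t-test power at the
        worst-case BH per-test level q/m (the smallest level BH can apply),
        so it lower-bounds the expected detection rate.
        """
        m, n_planted, n_per_group, delta = 500, 50, 10, 3.0
        genes = [f"g{i}" for i in range(m)]
        epi_vals = rng.normal(6, 1, (m, n_per_group))
        stro_vals = rng.normal(6, 1, (m, n_per_group))
        epi_vals[:n_planted] += delta
        epi = ExpressionMatrix(genes, [f"e{i}" for i in range(n_per_group)], epi_vals)
        stro = ExpressionMatrix(genes, [f"t{i}" for i in range(n_per_group)], stro_vals)
        table = differential_expression(epi, stro, fdr_threshold=0.1)
        detected = table.loc[genes[:n_planted], "significant"].mean()
        power = TTestIndPower().power(
            effect_size=delta, nobs1=n_per_group, alpha=0.1 / m, ratio=1.0
        )
        assert detected >= power - 0.05

    def test_bh_significant_set_nests_with_threshold(self, rng):
        m = 200
        epi_vals = rng.normal(6, 1, (m, 8))
        stro_vals = rng.normal(6, 1, (m, 8))
        epi_vals[:40] += rng.uniform(0.5, 2.0, (40, 1))
        genes = [f"g{i}" for i in range(m)]
        epi = ExpressionMatrix(genes, [f"e{i}" for i in range(8)], epi_vals)
        stro = ExpressionMatrix(genes, [f"t{i}" for i in range(8)], stro_vals)
        sets = []
        for q in (0.01, 0.05, 0.10, 0.25):
            table = differential_expression(epi, stro, fdr_threshold=q)
            sets.append(set(table.index[table["significant"]]))
        for smaller, larger in zip(sets[:-1], sets[1:]):
            assert smaller <= larger


class TestConcordance:
    def _tables(self, directions, regulations):
        import pandas as pd

        genes = [f"g{i}" for i in range(len(directions))]
        corr = pd.DataFrame({"direction": directions}, index=genes)
        degs = pd.DataFrame({"regulation": regulations}, index=genes)
        return corr, degs

    def test_all_concordant(self):
        corr, degs = self._tables(["positive"] * 4, ["up"] * 4)
        res = concordance_score(corr, degs)
        assert (res.k, res.s, res.score) == (4, 4, 1.0)

    def test_half_concordant_by_definition(self):
        corr, degs = self._tables(
            ["positive", "positive", "negative", "negative"],
            ["up", "down", "down", "up"],
        )
        res = concordance_score(corr, degs)
        assert (res.k, res.s, res.score) == (4, 2, 0.5)

    def test_empty_overlap_is_degenerate(self):
        corr, degs = self._tables([], [])
        res = concordance_score(corr, degs)
        assert res.k == 0
        assert np.isnan(res.score)
        assert res.p_value == 1.0

    @pytest.mark.parametrize(
        "k,s,expected",
        [(1, 1, 0.5), (2, 0, 1.0), (4, 4, 0.0625)],
    )
    def test_pvalue_examples_match_enumeration(self, k, s, expected):
        assert concordance_pvalue(k, s, 0.5) == pytest.approx(expected, abs=1e-12)
        assert brute_force_upper_tail(k, s) == pytest.approx(expected, abs=1e-12)

    def test_pvalue_matches_enumeration_k_up_to_10(self):
        for k in range(1, 11):
            for s in range(k + 1):
                assert concordance_pvalue(k, s, 0.5) == pytest.approx(
                    brute_force_upper_tail(k, s), abs=1e-12
                )

    def test_pvalue_non_increasing_in_s(self):
        for k in (5, 20, 1000):
            p = [concordance_pvalue(k, s, 0.5) for s in range(k + 1)]
            assert all(a >= b for a, b in zip(p[:-1], p[1:]))

    def test_pvalue_large_k_stays_finite_and_tiny(self):
        p = concordance_pvalue(100_000, 99_000, 0.5)
        assert 0.0 <= p < 1e-300 or p == 0.0

    def test_pvalue_input_validation(self):
        with pytest.raises(ValueError):
            concordance_pvalue(3, 4)
        with pytest.raises(ValueError):
            concordance_pvalue(3, 1, pe=0.0)
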