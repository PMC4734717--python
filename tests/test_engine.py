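"""Chi-square, fixed-margin sampling, Monte-Carlo p, Fisher exact test.

Independent oracles: scipy.stats.chi2_contingency / chisquare /
fisher_exact / contingency.odds_ratio and direct hypergeometric
enumeration.  The engine never calls those routines itself.
"""

import math

import numpy as np
import pytest
import scipy.stats as sps
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio

from paleoassoc import (
    ContingencyTable,
    EngineConfig,
    chi_square,
    expected_counts,
    fisher_exact_2x2,
    monte_carlo_p,
    sample_fixed_margins,
)

from paleoassoc.curation import DegenerateDesignError


def tab(counts, rows=None, cols=None):
    counts = np.atleast_2d(np.asarray(counts, dtype=int))
    if counts.shape[0] == 1:
        counts = counts.T
    r, c = counts.shape
    return ContingencyTable(
        row_labels=tuple(rows or [f"r{i}" for i in range(r)]),
        col_labels=tuple(cols or [f"c{j}" for j in range(c)]),
        counts=counts,
    )


def random_tables(rng, n, shape=(3, 2), lam=12.0):
    out = []
    while len(out) < n:
        counts = rng.poisson(lam, size=shape)
        try:
            out.append(tab(counts))
        except (DegenerateDesignError, ValueError):
            continue
    return out


class TestExpectedCounts:
    def test_single_column_is_uniform(self):
        e = expected_counts(tab([3, 10, 16]))
        assert np.allclose(e, 29 / 3)

    def test_two_column_product_rule(self):
        e = expected_counts(tab([[14, 77], [8, 88]]))
        assert math.isclose(e[0, 0], 91 * 22 / 187)
        assert math.isclose(e[1, 1], 96 * 165 / 187)

    def test_uniform_table(self):
        assert np.allclose(expected_counts(tab([[5, 5], [5, 5]])), 5.0)


class TestChiSquare:
    @pytest.mark.parametrize(
        "counts, stat, p",
        [
            ([3, 10, 16], 8.7586, 0.01253),
            ([[14, 77], [8, 88]], 2.2376, 0.1347),  # no Yates correction
            ([26, 37, 15, 41, 12, 52], 39.918, 1.55e-07),
        ],
    )
    def test_published_examples(self, counts, stat, p):
        result = chi_square(tab(counts))
        assert result.statistic == pytest.approx(stat, abs=5e-5)
        assert result.p_asymptotic == pytest.approx(p, rel=5e-3)

    def test_df_rules(self):
        assert chi_square(tab([3, 10, 16])).df == 2
        assert chi_square(tab([[1, 2], [3, 4], [5, 6]])).df == 2
        assert chi_square(tab([[14, 77], [8, 88]])).df == 1

    def test_statistic_is_sum_of_squared_residuals(self):
        rng = np.random.default_rng(5)
        for table in random_tables(rng, 25) + random_tables(rng, 10, (4, 1)):
            r = chi_square(table)
            assert r.statistic == pytest.approx((r.residuals**2).sum(), rel=1e-12)

    def test_df2_closed_form(self):
        for table in ([3, 10, 16], [[3, 63], [10, 56], [16, 65]]):
            r = chi_square(tab(table))
            assert r.df == 2
            assert r.p_asymptotic == pytest.approx(math.exp(-r.statistic / 2), rel=1e-12)

    def test_invariances(self):
        t = tab([[6, 12], [8, 52]])
        assert chi_square(t).statistic == pytest.approx(
            chi_square(tab([[6, 8], [12, 52]])).statistic, rel=1e-12
        )  # transpose
        assert chi_square(t).statistic == pytest.approx(
            chi_square(tab([[8, 52], [6, 12]])).statistic, rel=1e-12
        )  # row swap

    def test_agreement_with_reference_implementation(self):
        rng = np.random.default_rng(42)
        for table in random_tables(rng, 1000, shape=(3, 2)):
            ours = chi_square(table)
            stat, p, df, expected = sps.chi2_contingency(
                table.counts, correction=False
            )
            assert ours.statistic == pytest.approx(stat, abs=1e-9)
            assert ours.p_asymptotic == pytest.approx(p, abs=1e-9)
            assert ours.df == df
            assert np.allclose(ours.expected, expected, atol=1e-9)

    def test_goodness_of_fit_matches_reference(self):
        rng = np.random.default_rng(7)
        for table in random_tables(rng, 200, shape=(4, 1)):
            ours = chi_square(table)
            stat, p = sps.chisquare(table.counts[:, 0])
            assert ours.statistic == pytest.approx(stat, abs=1e-9)
            assert ours.p_asymptotic == pytest.approx(p, abs=1e-9)

    def test_mc_trigger_rule(self):
        cfg = EngineConfig(seed=0)
        assert chi_square(tab([2, 5, 7]), cfg).mc_used      # expected 14/3 < 5
        assert not chi_square(tab([3, 10, 16]), cfg).mc_used  # expected 29/3


class TestSampleFixedMargins:
    def test_margins_always_preserved(self):
        rng = np.random.default_rng(1)
        for rows, cols in [((27, 39), (3, 63)), ((5, 9, 4), (10, 8)),
                           ((18, 60), (14, 64))]:
            for _ in range(500):
                draw = sample_fixed_margins(rows, cols, rng)
                assert tuple(draw.sum(axis=1)) == rows
                assert tuple(draw.sum(axis=0)) == cols
                assert (draw >= 0).all()

    def test_degenerate_single_cell(self):
        draw = sample_fixed_margins([5], [5], np.random.default_rng(0))
        assert draw.tolist() == [[5]]

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            sample_fixed_margins([5, 5], [3, 3], np.random.default_rng(0))

    def test_2x2_cell_follows_hypergeometric(self):
        # top-left cell of tables with margins (18,60) x (14,64) is
        # hypergeometric(N=78, K=14, n=18); goodness-of-fit on 20k draws
        rng = np.random.default_rng(123)
        n_draws = 20_000
        cells = np.array(
            [sample_fixed_margins((18, 60), (14, 64), rng)[0, 0]
             for _ in range(n_draws)]
        )
        support = np.arange(0, 15)
        pmf = sps.hypergeom.pmf(support, 78, 14, 18)
        observed = np.bincount(cells, minlength=15)
        keep = pmf * n_draws >= 5
        stat, p = sps.chisquare(
            observed[keep], pmf[keep] / pmf[keep].sum() * observed[keep].sum()
        )
        assert p > 1e-3

    def test_matches_scipy_random_table_distribution(self):
        # cross-check against scipy's Patefield sampler on a 3x2 margin
        rng = np.random.default_rng(9)
        rows, cols = (8, 12, 6), (11, 15)
        ours = np.array(
            [sample_fixed_margins(rows, cols, rng)[0, 0] for _ in range(8000)]
        )
        ref = sps.random_table(rows, cols).rvs(
            8000, method="patefield", random_state=np.random.default_rng(10)
        )[:, 0, 0]
        assert abs(ours.mean() - ref.mean()) < 0.1
        assert abs(ours.var() - ref.var()) < 0.2


class TestMonteCarloP:
    def test_addone_formula_at_b1(self):
        # with one replicate whose statistic is below the observed one,
        # p = (1 + 0) / (1 + 1) = 1/2
        table = tab([10, 0])
        cfg = EngineConfig(b=1, seed=3)
        rng = np.random.default_rng(3)
        rep = rng.multinomial(10, [0.5, 0.5])
        assert rep.tolist() not in ([10, 0], [0, 10])  # fixed-seed replicate
        assert monte_carlo_p(table, cfg) == 0.5

    def test_deterministic_under_seed(self):
        table = tab([[1, 26], [2, 37]])
        cfg = EngineConfig(b=500, seed=77)
        assert monte_carlo_p(table, cfg) == monte_carlo_p(table, cfg)

    def test_published_monte_carlo_value(self):
        # coastal taxa counts of the smallest dataset variant: printed
        # Monte-Carlo p 0.2894 at B = 2000
        p = monte_carlo_p(tab([2, 5, 7]), EngineConfig(b=2000, seed=4))
        se = math.sqrt(0.2894 * (1 - 0.2894) / 2000)
        assert abs(p - 0.2894) < 3 * se

    def test_p_within_unit_interval_and_consistent(self):
        table = tab([[6, 12], [8, 52]])
        p = monte_carlo_p(table, EngineConfig(b=999, seed=5))
        assert 1 / 1000 <= p <= 1.0


class TestFisher:
    def test_published_odds_ratio_and_p(self):
        r = fisher_exact_2x2(tab([[6, 12], [8, 52]]))
        assert r.or_cmle == pytest.approx(3.19102, abs=5e-4)
        assert r.p_two_sided == pytest.approx(0.07777, abs=5e-5)

    def test_zero_cell_gives_zero_odds_ratio(self):
        r = fisher_exact_2x2(tab([[0, 15], [9, 41]]))
        assert r.or_cmle == 0.0
        assert r.p_two_sided == pytest.approx(0.10334, abs=5e-5)

    def test_symmetric_table(self):
        r = fisher_exact_2x2(tab([[5, 5], [5, 5]]))
        assert r.p_two_sided == 1.0
        assert r.or_cmle == pytest.approx(1.0, abs=1e-8)

    def test_two_sided_p_of_modal_table_is_one_but_tail_is_not(self):
        # when the observed table is the most probable one the two-sided
        # p is exactly 1; the upper tail still carries information
        r = fisher_exact_2x2(tab([[1, 26], [2, 37]]))
        assert r.p_two_sided == 1.0
        assert r.p_greater == pytest.approx(0.8003, abs=5e-5)
        assert r.or_cmle == pytest.approx(0.71509, abs=5e-4)

    def test_transpose_and_row_swap_invariances(self):
        a = fisher_exact_2x2(tab([[6, 12], [8, 52]]))
        transposed = fisher_exact_2x2(tab([[6, 8], [12, 52]]))
        swapped = fisher_exact_2x2(tab([[8, 52], [6, 12]]))
        assert transposed.p_two_sided == pytest.approx(a.p_two_sided, rel=1e-12)
        assert swapped.p_two_sided == pytest.approx(a.p_two_sided, rel=1e-12)
        assert swapped.or_cmle == pytest.approx(1 / a.or_cmle, rel=1e-6)
        zero = fisher_exact_2x2(tab([[0, 15], [9, 41]]))
        inv = fisher_exact_2x2(tab([[9, 41], [0, 15]]))
        assert zero.or_cmle == 0.0 and math.isinf(inv.or_cmle)

    def test_non_2x2_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(tab([[1, 2], [3, 4], [5, 6]]))

    def test_agreement_with_reference_implementation(self):
        rng = np.random.default_rng(11)
        for table in random_tables(rng, 300, shape=(2, 2), lam=8.0):
            ours = fisher_exact_2x2(table)
            _, p_ref = sps.fisher_exact(table.counts)
            assert ours.p_two_sided == pytest.approx(p_ref, abs=1e-9)
            or_ref = scipy_odds_ratio(table.counts, kind="conditional").statistic
            if or_ref == 0 or math.isinf(or_ref):
                assert ours.or_cmle == or_ref
            else:
                assert ours.or_cmle == pytest.approx(or_ref, rel=1e-6, abs=1e-9)

    def test_one_sided_tails_sum_correctly(self):
        r = fisher_exact_2x2(tab([[6, 12], [8, 52]]))
        # P(X <= x) + P(X >= x) = 1 + P(X = x)
        pmf_obs = sps.hypergeom.pmf(6, 78, 14, 18)
        assert r.p_less + r.p_greater == pytest.approx(1 + pmf_obs, rel=1e-9)
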