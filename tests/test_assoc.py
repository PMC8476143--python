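import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import intronevo as ie
from intronevo.assoc import mixture_threshold, pair_concordance


def ortholog_frame(rows):
    return pd.DataFrame(rows, columns=["set_id", "species", "has_intron",
                                       "selected", "duplicated", "go_terms"])


def make_pair_table(a_status, b_status):
    rows = []
    for i, (a, b) in enumerate(zip(a_status, b_status)):
        rows.append((f"og{i}", "spA", a, False, False, ""))
        rows.append((f"og{i}", "spB", b, False, False, ""))
    return ortholog_frame(rows)


class TestConcordance:
    def test_hand_worked_example(self):
        # n=10, 5 intron-containing in A, 4 in B, both in 4
        a = [True] * 5 + [False] * 5
        b = [True] * 4 + [False] * 6
        res = pair_concordance(make_pair_table(a, b), "spA", "spB")
        assert res.n == 10
        assert res.observed_both == 4
        assert res.expected_both == pytest.approx(2.0)
        assert res.ratio == pytest.approx(2.0)
        assert np.array_equal(res.table, [[4, 1], [0, 5]])

    def test_saturated_table_ratio_one(self):
        res = pair_concordance(make_pair_table([True] * 8, [True] * 8),
                               "spA", "spB")
        assert res.ratio == pytest.approx(1.0)

    def test_null_calibration(self):
        rng = np.random.default_rng(1)
        ratios, pvals = [], []
        for rep in range(200):
            a = rng.random(300) < 0.3
            b = rng.random(300) < 0.3
            res = pair_concordance(make_pair_table(a, b), "spA", "spB",
                                   seed=rep)
            ratios.append(res.ratio)
            pvals.append(res.p)
        se = np.std(ratios) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 1.0) < 3 * se
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_product_margins_give_exact_unity(self):
        # joint table equal to the product of its margins
        a = [True] * 6 + [True] * 2 + [False] * 3 + [False] * 1
        b = [True] * 6 + [False] * 2 + [True] * 3 + [False] * 1
        res = pair_concordance(make_pair_table(a, b), "spA", "spB")
        assert res.ratio == pytest.approx(1.0, abs=1e-12)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)


class TestBayesBinomCI:
    def test_near_certain_success(self):
        lo, hi = ie.bayes_binom_ci(1000, 1000, seed=1)
        assert hi >= 0.996

    def test_zero_successes(self):
        lo, hi = ie.bayes_binom_ci(0, 200, seed=2)
        assert lo < 0.01

    @pytest.mark.parametrize("s,n", [(0, 5), (3, 7), (50, 100), (99, 100)])
    def test_interval_well_formed(self, s, n):
        lo, hi = ie.bayes_binom_ci(s, n, seed=3)
        assert 0 <= lo <= hi <= 1

    def test_stable_under_more_draws(self):
        a = ie.bayes_binom_ci(30, 150, draws=1000, seed=4)
        b = ie.bayes_binom_ci(30, 150, draws=100000, seed=4)
        assert abs(a[0] - b[0]) < 0.01 and abs(a[1] - b[1]) < 0.01


class TestFlagEnrichment:
    def _table(self, cells):
        (ii_f, ii_nf), (ni_f, ni_nf) = cells
        rows = []
        i = 0
        for intron, flagged, count in [
            (True, True, ii_f), (True, False, ii_nf),
            (False, True, ni_f), (False, False, ni_nf),
        ]:
            for _ in range(count):
                rows.append((f"og{i}", "sp", intron, flagged, flagged, ""))
                i += 1
        return ortholog_frame(rows)

    def test_symmetric_table(self):
        res = ie.flag_enrichment(self._table([(10, 10), (10, 10)]), "sp",
                                 "duplicated")
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        table = np.array([[8, 2], [1, 9]])
        res = ie.flag_enrichment(self._table(table.tolist()), "sp",
                                 "duplicated", sidedness="two")
        # enumeration over all tables with the same margins
        r1, r2 = table.sum(axis=1)
        c1 = table[:, 0].sum()
        def prob(a):
            return (math.comb(r1, a) * math.comb(r2, c1 - a)
                    / math.comb(r1 + r2, c1))
        p_obs = prob(table[0, 0])
        p_two = sum(prob(a) for a in range(max(0, c1 - r2), min(r1, c1) + 1)
                    if prob(a) <= p_obs + 1e-12)
        assert res["p"] == pytest.approx(p_two, abs=1e-9)

    def test_odds_ratio_scale_invariant(self):
        r1 = ie.flag_enrichment(self._table([(8, 2), (1, 9)]), "sp",
                                "duplicated")
        r2 = ie.flag_enrichment(self._table([(16, 4), (2, 18)]), "sp",
                                "duplicated")
        assert r1["odds_ratio"] == pytest.approx(r2["odds_ratio"])

    def test_zero_margin_flagged(self):
        res = ie.flag_enrichment(self._table([(0, 10), (0, 10)]), "sp",
                                 "selected")
        assert res["p"] == 1.0 and not res["defined"]


class TestGoScore:
    def test_worked_example(self):
        assert ie.go_intron_score(7, 4, 250, 1000) == pytest.approx(3.0)

    def test_balanced_ratio_is_zero(self):
        # (xi+1)/sx == ci/sc
        assert ie.go_intron_score(xi=4, sx=10, ci=500, sc=1000) == pytest.approx(0.0)

    def test_monotone_in_intron_count(self):
        scores = [ie.go_intron_score(x, 5, 300, 1030) for x in range(10)]
        assert np.all(np.diff(scores) > 0)

    def test_summed_deviation_identity(self):
        # sum_terms sx * 2^score * (ci/sc) == sum_terms (xi + 1)
        rng = np.random.default_rng(5)
        ci, sc = 400, 1030
        lhs = rhs = 0.0
        for _ in range(30):
            sx = int(rng.integers(1, 40))
            xi = int(rng.integers(0, 100))
            score = ie.go_intron_score(xi, sx, ci, sc)
            lhs += sx * 2**score * (ci / sc)
            rhs += xi + 1
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_undefined_for_zero_species_introns(self):
        with pytest.raises(ValueError):
            ie.go_intron_score(5, 10, 0, 1000)


class TestMixtureThreshold:
    def _scores(self, seed, n=600):
        rng = np.random.default_rng(seed)
        noise = rng.lognormal(mean=3.0, sigma=0.4, size=n // 2)   # mode ~ 17
        signal = rng.normal(loc=300.0, scale=40.0, size=n // 2)
        return np.concatenate([noise, np.abs(signal)])

    def test_threshold_between_modes(self):
        res = mixture_threshold(self._scores(1), seed=2)
        assert not res["degenerate"]
        assert 25 < res["threshold"] < 300

    def test_em_loglik_monotone(self):
        res = mixture_threshold(self._scores(3), seed=4)
        path = res["fit"].loglik_path
        assert np.all(np.diff(path) >= -1e-6)

    def test_fit_dominates_generating_parameters(self):
        from intronevo.assoc import MixtureFit

        x = self._scores(5)
        res = mixture_threshold(x, seed=6)
        truth = MixtureFit(0.5, 3.0, 0.4, 300.0, 40.0, 0, 0, True)
        assert res["fit"].mixture_loglik_at(x) >= truth.mixture_loglik_at(x)

    def test_threshold_near_density_crossing(self):
        # analytic crossing of the generating weighted densities
        x = self._scores(7, n=4000)
        res = mixture_threshold(x, seed=8)
        grid = np.linspace(30, 290, 20000)
        f1 = 0.5 * stats.lognorm.pdf(grid, s=0.4, scale=np.exp(3.0))
        f2 = 0.5 * stats.norm.pdf(grid, 300.0, 40.0)
        crossing = grid[np.argmin(np.abs(f1 - f2))]
        assert res["threshold"] == pytest.approx(crossing, rel=0.10)

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            mixture_threshold(np.ones(10) + np.arange(10), seed=1)


class TestExpressionMetrics:
    def test_rpkm_example(self):
        assert ie.rpkm(10, 2000, 10**6) == pytest.approx(5.0)
        assert ie.rpkm(0, 2000, 10**6) == 0.0

    def test_rpkm_joint_scaling_invariance(self):
        assert ie.rpkm(10, 500, 10**6) == pytest.approx(ie.rpkm(70, 500, 7e6))

    def test_te_examples(self):
        assert ie.translation_efficiency(100, 10**6, 50, 10**6) == pytest.approx(2.0)
        assert ie.translation_efficiency(33, 10**6, 33, 10**6) == pytest.approx(1.0)
        assert math.isnan(ie.translation_efficiency(10, 100, 0, 100))

    def test_te_joint_library_scaling(self):
        a = ie.translation_efficiency(10, 1e6, 20, 2e6)
        b = ie.translation_efficiency(10, 3e6, 20, 6e6)
        assert a == pytest.approx(b)

    def test_expression_compare_identical_groups(self):
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(8)],
                "length": [1000] * 8,
                "has_intron": [True, False] * 4,
                "go_class": ["other"] * 8,
                "rna_count": [50, 50, 80, 80, 60, 60, 70, 70],
                "fp_count": [20, 20, 30, 30, 25, 25, 35, 35],
            }
        )
        res = ie.expression_compare(df)
        other = res["tests"].query("go_class == 'other'")
        assert np.allclose(other["t"], 0.0, atol=1e-12)
        assert np.allclose(other["p"], 1.0)

    def test_welch_matches_independent_oracle(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(60)],
                "length": rng.integers(500, 2000, 60),
                "has_intron": [True] * 30 + [False] * 30,
                "go_class": ["other"] * 60,
                "rna_count": rng.integers(10, 500, 60),
                "fp_count": rng.integers(10, 500, 60),
            }
        )
        res = ie.expression_compare(df)
        rec = res["records"]
        import statsmodels.stats.weightstats as ws

        for metric in ("rpkm", "te"):
            x = np.log2(rec.loc[rec.has_intron, metric].dropna() + 1)
            y = np.log2(rec.loc[~rec.has_intron, metric].dropna() + 1)
            t_ref, p_ref, _ = ws.ttest_ind(x, y, usevar="unequal")
            row = res["tests"].query(
                "go_class == 'other' and metric == @metric"
            ).iloc[0]
            assert row["t"] == pytest.approx(t_ref, abs=1e-9)
            assert row["p"] == pytest.approx(p_ref, abs=1e-9)
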