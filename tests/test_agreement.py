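"""Kendall's W (tie-corrected) and Wilks'-lambda group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from mcdm_survey.agreement import (
    AgreementError,
    RankScoreTable,
    concordance_by_category,
    holm_adjust,
    kendall_w,
    rank_scores,
    univariate_group_tests,
    wilks_manova,
)
from mcdm_survey.pcm import PriorityVector
from mcdm_survey.synthetic import GeneratorSpec, generate_survey


def brute_force_w(ranks: np.ndarray) -> float:
    """Naive evaluation of the tie-corrected concordance formula.

    Rank sums, their squared deviations, and the tie correction are all
    accumulated with explicit loops over judges, items and tie groups.
    """
    m, n = ranks.shape
    sums = [0.0] * n
    for j in range(m):
        for i in range(n):
            sums[i] += ranks[j, i]
    mean = sum(sums) / n
    ss = sum((s - mean) ** 2 for s in sums)
    f = 0.0
    for j in range(m):
        seen = {}
        for i in range(n):
            seen[ranks[j, i]] = seen.get(ranks[j, i], 0) + 1
        for t in seen.values():
            f += t**3 - t
    return 12.0 * ss / (m * m * (n**3 - n) - m * f)


def table_from(ranks, judges=None):
    ranks = np.asarray(ranks, dtype=float)
    m, n = ranks.shape
    return RankScoreTable(
        items=tuple(f"i{k}" for k in range(n)),
        judges=tuple(judges or (f"j{k}" for k in range(m))),
        ranks=ranks,
    )


def random_midrank_row(rng, n):
    vals = rng.integers(0, n - 1, size=n).astype(float)  # forces ties
    return stats.rankdata(vals, method="average")


class TestRankScores:
    def test_weights_map_to_ascending_ranks(self):
        pv = {
            "a": PriorityVector(items=("x", "y", "z"), weights=np.array([0.5, 0.3, 0.2]), lambda_max=3),
            "b": PriorityVector(items=("x", "y", "z"), weights=np.array([0.2, 0.3, 0.5]), lambda_max=3),
        }
        t = rank_scores(pv)
        np.testing.assert_array_equal(t.ranks[0], [3, 2, 1])
        np.testing.assert_array_equal(t.ranks[1], [1, 2, 3])

    def test_ties_share_average_rank(self):
        pv = {
            "a": PriorityVector(items=("x", "y", "z"), weights=np.array([0.4, 0.4, 0.2]), lambda_max=3),
            "b": PriorityVector(items=("x", "y", "z"), weights=np.array([0.4, 0.4, 0.2]), lambda_max=3),
        }
        t = rank_scores(pv)
        np.testing.assert_array_equal(t.ranks[0], [2.5, 2.5, 1])

    def test_row_sums_are_conserved(self):
        rng = np.random.default_rng(1)
        n = 7
        pv = {}
        for k in range(5):
            w = rng.dirichlet(np.ones(n))
            pv[f"j{k}"] = PriorityVector(
                items=tuple(f"i{q}" for q in range(n)), weights=w, lambda_max=n
            )
        t = rank_scores(pv)
        np.testing.assert_allclose(t.ranks.sum(axis=1), n * (n + 1) / 2)


class TestKendallW:
    def test_identical_rankings_give_one(self):
        ranks = np.tile(np.arange(1, 8, dtype=float), (5, 1))
        res = kendall_w(table_from(ranks))
        assert res.w == pytest.approx(1.0, abs=1e-12)
        assert res.f_correction == 0.0

    def test_reversed_pair_gives_zero(self):
        ranks = np.array([[1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1]], dtype=float)
        res = kendall_w(table_from(ranks))
        assert res.w == pytest.approx(0.0, abs=1e-12)
        assert res.ss == 0.0

    def test_tied_table_matches_brute_force(self):
        ranks = np.array(
            [[1.5, 1.5, 3, 4], [2, 1, 4, 3], [1, 2, 3, 4]], dtype=float
        )
        res = kendall_w(table_from(ranks))
        assert res.f_correction == pytest.approx(2.0 ** 3 - 2.0)
        assert res.w == pytest.approx(brute_force_w(ranks), abs=1e-12)

    def test_many_random_tied_tables_match_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            m = int(rng.integers(2, 7))
            n = int(rng.integers(3, 8))
            ranks = np.array([random_midrank_row(rng, n) for _ in range(m)])
            try:
                res = kendall_w(table_from(ranks))
            except AgreementError:
                continue  # fully tied degenerate table
            assert res.w == pytest.approx(brute_force_w(ranks), abs=1e-12)
            assert -1e-12 <= res.w <= 1.0 + 1e-12

    def test_no_ties_reduces_to_classic_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m, n = 4, 6
            ranks = np.array([rng.permutation(n) + 1.0 for _ in range(m)])
            res = kendall_w(table_from(ranks))
            classic = 12.0 * res.ss / (m * m * (n**3 - n))
            assert res.w == pytest.approx(classic, abs=1e-12)
            assert res.f_correction == 0.0

    def test_matches_friedman_statistic_without_ties(self):
        rng = np.random.default_rng(3)
        m, n = 6, 8
        data = rng.normal(size=(m, n))
        ranks = np.array([stats.rankdata(row) for row in data])
        res = kendall_w(table_from(ranks))
        chi2_friedman, _ = stats.friedmanchisquare(*[data[:, i] for i in range(n)])
        assert res.chi2 == pytest.approx(chi2_friedman, rel=1e-10)

    def test_null_mean_is_one_over_m(self):
        rng = np.random.default_rng(4)
        m, n = 19, 9
        ws = []
        for _ in range(500):
            ranks = np.array([rng.permutation(n) + 1.0 for _ in range(m)])
            ws.append(kendall_w(table_from(ranks)).w)
        ws = np.asarray(ws)
        se = ws.std(ddof=1) / np.sqrt(ws.size)
        assert abs(ws.mean() - 1.0 / m) < 3 * se

    def test_significance_flag_matches_gamma_tail(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m, n = int(rng.integers(3, 10)), int(rng.integers(3, 9))
            ranks = np.array([rng.permutation(n) + 1.0 for _ in range(m)])
            res = kendall_w(table_from(ranks))
            # independent tail computation via the regularized incomplete gamma
            p = float(special.gammaincc(res.df / 2.0, res.chi2 / 2.0))
            assert res.p_value == pytest.approx(p, abs=1e-12)
            assert res.significant == (p < 0.05)

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(6)
        ranks = np.array([rng.permutation(6) + 1.0 for _ in range(4)])
        base = kendall_w(table_from(ranks)).w
        perm_items = rng.permutation(6)
        perm_judges = rng.permutation(4)
        shuffled = ranks[np.ix_(perm_judges, perm_items)]
        assert kendall_w(table_from(shuffled)).w == pytest.approx(base, abs=1e-12)

    def test_duplicating_the_whole_panel_leaves_w_unchanged(self):
        # SS scales by 4 and the tie-corrected denominator by 4 as well, so
        # replicating every judge exactly once cannot move W
        rng = np.random.default_rng(7)
        for _ in range(100):
            m, n = int(rng.integers(2, 6)), int(rng.integers(3, 7))
            ranks = np.array([random_midrank_row(rng, n) for _ in range(m)])
            try:
                w0 = kendall_w(table_from(ranks)).w
            except AgreementError:
                continue
            w1 = kendall_w(table_from(np.vstack([ranks, ranks]))).w
            assert w1 == pytest.approx(w0, abs=1e-12)

    def test_duplicating_a_unanimous_judge_keeps_perfect_agreement(self):
        ranks = np.tile(np.arange(1, 7, dtype=float), (3, 1))
        dup = np.vstack([ranks, ranks[0]])
        assert kendall_w(table_from(dup)).w == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_all_tied_table_rejected(self):
        ranks = np.full((3, 4), 2.5)
        with pytest.raises(AgreementError, match="degenerate"):
            kendall_w(table_from(ranks))

    def test_permutation_p_value_agrees_with_chi2_roughly(self):
        ranks = np.tile(np.arange(1, 6, dtype=float), (4, 1))
        res_chi2 = kendall_w(table_from(ranks), method="chi2")
        res_perm = kendall_w(table_from(ranks), method="permutation", n_permutations=2000, rng=0)
        assert res_perm.significant and res_chi2.significant
        assert res_perm.p_value < 0.01


class TestConcordanceByCategory:
    def test_full_agreement_gives_w_one_everywhere(self, small_protocol):
        spec = GeneratorSpec(
            protocol=small_protocol,
            n_modelers=5,
            seed=0,
            judgment_noise_sigma=0.0,
            agreement=1.0,
        )
        bundle, _ = generate_survey(spec)
        results = concordance_by_category(bundle)
        assert set(results) == set(small_protocol.category_codes) | {"CATEGORIES"}
        for res in results.values():
            assert res.w == pytest.approx(1.0, abs=1e-9)

    def test_requires_two_judges(self, small_protocol):
        spec = GeneratorSpec(protocol=small_protocol, n_modelers=2, seed=0)
        bundle, _ = generate_survey(spec)
        with pytest.raises(AgreementError, match="at least 2"):
            concordance_by_category(bundle, retained=[bundle.modeler_ids[0]])


class TestWilksManova:
    def test_identical_group_means_give_lambda_one(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(4, 3))
        x = np.vstack([base, base])  # group means identical by construction
        groups = ["g1"] * 4 + ["g2"] * 4
        res = wilks_manova(x, groups)
        assert res.wilks_lambda == pytest.approx(1.0, abs=1e-12)
        assert not res.significant

    def test_univariate_case_equals_anova_ratio(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 10), rng.normal(1.5, 1, 10)])[:, None]
        groups = ["a"] * 10 + ["b"] * 10
        res = wilks_manova(x, groups)
        grand = x.mean()
        ssw = sum(((x[:10] - x[:10].mean()) ** 2).sum() for _ in [0]) + ((x[10:] - x[10:].mean()) ** 2).sum()
        sst = ((x - grand) ** 2).sum()
        assert res.wilks_lambda == pytest.approx(float(ssw / sst), abs=1e-10)

    def test_matches_statsmodels_manova(self):
        statsmodels = pytest.importorskip("statsmodels.multivariate.manova")
        rng = np.random.default_rng(3)
        x = np.vstack(
            [
                rng.normal(0, 1, size=(8, 2)),
                rng.normal([1.0, -0.5], 1, size=(7, 2)),
            ]
        )
        groups = np.array(["a"] * 8 + ["b"] * 7)
        res = wilks_manova(x, groups)
        exog = np.column_stack([np.ones(15), (groups == "b").astype(float)])
        mv = statsmodels.MANOVA(endog=x, exog=exog)
        frame = mv.mv_test([("group", np.array([[0.0, 1.0]]))]).results["group"]["stat"]
        lam = float(frame.loc["Wilks' lambda", "Value"])
        f = float(frame.loc["Wilks' lambda", "F Value"])
        p = float(frame.loc["Wilks' lambda", "Pr > F"])
        assert res.wilks_lambda == pytest.approx(lam, abs=1e-8)
        assert res.f_stat == pytest.approx(f, rel=1e-6)
        assert res.p_value == pytest.approx(p, abs=1e-8)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(12, 3))
        x[6:] += [0.8, -0.4, 0.2]
        groups = ["a"] * 6 + ["b"] * 6
        lam = wilks_manova(x, groups).wilks_lambda
        shifted = x + np.array([10.0, -3.0, 100.0])
        scaled = x * np.array([2.0, 0.5, 7.0])
        assert wilks_manova(shifted, groups).wilks_lambda == pytest.approx(lam, abs=1e-10)
        assert wilks_manova(scaled, groups).wilks_lambda == pytest.approx(lam, abs=1e-10)

    def test_too_many_features_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 10))
        groups = ["a"] * 3 + ["b"] * 3
        with pytest.raises(AgreementError, match="singular"):
            wilks_manova(x, groups)

    def test_small_groups_rejected(self):
        x = np.zeros((3, 1))
        with pytest.raises(AgreementError, match="fewer than 2"):
            wilks_manova(x, ["a", "a", "b"])


class TestUnivariateFollowups:
    def test_matches_scipy_anova_and_holm_is_monotone(self):
        rng = np.random.default_rng(6)
        x = pd.DataFrame(
            {
                "v1": np.concatenate([rng.normal(0, 1, 8), rng.normal(2, 1, 8)]),
                "v2": rng.normal(0, 1, 16),
            }
        )
        groups = ["a"] * 8 + ["b"] * 8
        res = univariate_group_tests(x, groups)
        f, p = stats.f_oneway(x["v1"][:8], x["v1"][8:])
        assert res.loc[res.variable == "v1", "p_value"].iloc[0] == pytest.approx(p)
        res_h = univariate_group_tests(x, groups, holm=True)
        assert (res_h["p_adjusted"] >= res_h["p_value"] - 1e-15).all()

    def test_holm_adjustment_values(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])
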