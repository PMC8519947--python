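import numpy as np
import pandas as pd
import pytest
from scipy import stats

from passig.datamodel import ExpressionMatrix, GeneSetCollection
from passig.diffexpr import RankedList
from passig.enrichment import (DegenerateSetError, GseaResult,
                               gsea_es, gsea_permutation, select_candidates,
                               ssgsea_score, welch_fdr)


def brute_force_es(genes, scores, geneset, p=1.0):
    """Direct O(N) running-sum recomputation of the enrichment statistic."""
    n = len(genes)
    hits = [g in geneset for g in genes]
    n_hit = sum(hits)
    n_r = sum(abs(s) ** p for s, h in zip(scores, hits) if h)
    running, cur = [], 0.0
    for s, h in zip(scores, hits):
        if h:
            cur += (abs(s) ** p / n_r) if n_r > 0 else 1.0 / n_hit
        else:
            cur -= 1.0 / (n - n_hit)
        running.append(cur)
    best = max(running, key=lambda v: (abs(v), v))
    return best, running


def ranked(scores, genes=None):
    genes = genes or [f"g{i + 1}" for i in range(len(scores))]
    return RankedList(genes, np.asarray(scores, dtype=float))


class TestGseaEs:
    def test_single_top_hit_is_one(self):
        es, running, le, peak = gsea_es(ranked([5, 4, 3, 2, 1]), {"g1"})
        assert es == pytest.approx(1.0)
        assert le == ["g1"] and peak == 0

    def test_single_bottom_hit_is_minus_one(self):
        es, running, le, peak = gsea_es(ranked([5, 4, 3, 2, 1]), {"g5"})
        assert es == pytest.approx(-1.0)
        assert peak == 3 and le == ["g5"]

    def test_top_two_hits(self):
        # P_hit(2) = (5+4)/9 = 1, P_miss(2) = 0
        es, running, le, peak = gsea_es(ranked([5, 4, 3, 2, 1]), {"g1", "g2"})
        assert es == pytest.approx(1.0)
        assert peak == 1 and le == ["g1", "g2"]

    def test_running_sum_ends_at_zero(self):
        rng = np.random.default_rng(0)
        scores = np.sort(rng.normal(size=30))[::-1]
        rl = ranked(scores)
        _, running, _, _ = gsea_es(rl, {"g3", "g7", "g20"})
        assert running[-1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(5, 100))
            scores = np.sort(rng.normal(size=n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            m = int(rng.integers(1, n))
            S = set(rng.choice(genes, size=m, replace=False))
            es, running, _, _ = gsea_es(RankedList(genes, scores), S)
            es_bf, running_bf = brute_force_es(genes, scores, S)
            assert abs(es - es_bf) < 1e-12
            np.testing.assert_allclose(running, running_bf, atol=1e-12)

    def test_invariant_to_relabeling_non_set_genes(self):
        scores = [4.0, 3.0, 2.0, 1.0, 0.5]
        rl1 = ranked(scores, ["a", "b", "c", "d", "e"])
        rl2 = ranked(scores, ["a", "X", "c", "Y", "Z"])
        s1, *_ = gsea_es(rl1, {"a", "c"})
        s2, *_ = gsea_es(rl2, {"a", "c"})
        assert s1 == s2

    def test_degenerate_sets_rejected(self):
        rl = ranked([3, 2, 1])
        with pytest.raises(DegenerateSetError):
            gsea_es(rl, {"zzz"})
        with pytest.raises(DegenerateSetError):
            gsea_es(rl, {"g1", "g2", "g3"})


class TestGseaPermutation:
    def test_exact_enumeration_on_tiny_instance(self):
        # |S|=1 over 5 genes: the permutation null has 5 equally likely ES
        rl = ranked([5, 4, 3, 2, 1])
        es_obs, *_ = gsea_es(rl, {"g1"})
        null_es = [gsea_es(rl, {g})[0] for g in rl.genes]
        same = [e for e in null_es if (e > 0) == (es_obs >= 0)]
        p_exact = sum(abs(e) >= abs(es_obs) for e in same) / len(same)
        _, _, p_mc, _ = gsea_permutation(rl, {"g1"}, n_perm=10000, seed=3)
        # binomial 99% CI of the Monte-Carlo estimate around p_exact
        half = 2.58 * np.sqrt(p_exact * (1 - p_exact) / 10000) + 2e-4
        assert abs(p_mc - p_exact) <= half + 1e-9

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(5)
        n = 200
        scores = np.sort(rng.normal(size=n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        rl = RankedList(genes, scores)
        ps = []
        for t in range(200):
            m = int(rng.integers(5, 30))
            S = set(rng.choice(genes, size=m, replace=False))
            ps.append(gsea_permutation(rl, S, n_perm=1000, seed=9000 + t)[2])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_same_seed_is_deterministic(self):
        rl = ranked(np.linspace(3, -3, 50))
        a = gsea_permutation(rl, {"g1", "g9", "g30"}, n_perm=500, seed=4)
        b = gsea_permutation(rl, {"g1", "g9", "g30"}, n_perm=500, seed=4)
        assert a == b

    def test_nes_sign_matches_es(self):
        rl = ranked(np.linspace(3, -3, 60))
        es, nes, p, _ = gsea_permutation(rl, {"g1", "g2", "g3"}, n_perm=500,
                                         seed=1)
        assert np.sign(nes) == np.sign(es)
        es2, nes2, p2, _ = gsea_permutation(rl, {"g58", "g59", "g60"},
                                            n_perm=500, seed=1)
        assert np.sign(nes2) == np.sign(es2) == -1


def make_results(specs):
    return [GseaResult(pathway=name, size=10, es=es, nes=nes, pvalue=p,
                       padj=q, leading_edge=["x"], peak_index=0)
            for name, es, nes, p, q in specs]


class TestSelectCandidates:
    def test_truncates_to_top_k_by_nes(self):
        res = make_results([(f"P{i}", 0.5, 3.0 - i * 0.01, 0.001, 0.01)
                            for i in range(98)])
        cand = select_candidates(res, top_k=15)
        assert len(cand.pathways) == 15
        assert cand.pathways == [f"P{i}" for i in range(15)]

    def test_all_negative_es_is_empty_error(self):
        res = make_results([("P1", -0.5, -2.0, 0.001, 0.01)])
        with pytest.raises(Exception, match="no pathway"):
            select_candidates(res)

    def test_fewer_survivors_than_k(self):
        res = make_results([("A", 0.4, 1.5, 0.01, 0.02),
                            ("B", 0.6, 2.5, 0.001, 0.01),
                            ("C", 0.2, 0.9, 0.5, 0.6)])
        cand = select_candidates(res, top_k=15)
        assert cand.pathways == ["B", "A"]

    def test_stable_under_input_permutation(self):
        res = make_results([(f"P{i}", 0.5, 2.0 + (i % 5) * 0.1, 0.001, 0.01)
                            for i in range(20)])
        c1 = select_candidates(res)
        c2 = select_candidates(list(reversed(res)))
        assert c1.pathways == c2.pathways


def brute_force_ssgsea(expr_col, gene_ids, geneset, alpha):
    """Independent double loop over ranked positions (weighted ECDF gap)."""
    ranks = stats.rankdata(expr_col, method="average")
    order = sorted(range(len(gene_ids)),
                   key=lambda i: (-ranks[i], gene_ids[i]))
    inset = [gene_ids[i] in geneset for i in order]
    w = [abs(ranks[i]) ** alpha for i in order]
    denom_in = sum(wi for wi, h in zip(w, inset) if h)
    n_out = sum(1 for h in inset if not h)
    total = 0.0
    for i in range(len(order)):
        cdf_in = sum(wi for wi, h in zip(w[: i + 1], inset[: i + 1]) if h) / denom_in
        cdf_out = sum(1 for h in inset[: i + 1] if not h) / n_out
        total += cdf_in - cdf_out
    return total


class TestSsgsea:
    def test_identical_columns_identical_scores(self):
        rng = np.random.default_rng(0)
        col = rng.gamma(2, 50, size=30)
        df = pd.DataFrame({"a": col, "b": col},
                          index=[f"g{i}" for i in range(30)])
        tpm = ExpressionMatrix(df, unit="tpm")
        gs = GeneSetCollection({"S": {"g1", "g5", "g9"}})
        sc = ssgsea_score(tpm, gs)
        assert sc.loc["S", "a"] == sc.loc["S", "b"]

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        col = rng.gamma(2, 50, size=40)
        df = pd.DataFrame({"a": col, "b": rng.gamma(2, 50, size=40)},
                          index=[f"g{i}" for i in range(40)])
        gs = GeneSetCollection({"S": {f"g{i}" for i in range(0, 12, 2)}})
        s1 = ssgsea_score(ExpressionMatrix(df, unit="tpm"), gs, normalize=False)
        df2 = df.copy()
        df2["a"] = np.exp(df2["a"] / df2["a"].max() * 3)  # strictly increasing
        s2 = ssgsea_score(ExpressionMatrix(df2, unit="tpm"), gs, normalize=False)
        assert s1.loc["S", "a"] == pytest.approx(s2.loc["S", "a"], abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(20):
            n = int(rng.integers(5, 40))
            genes = [f"g{i}" for i in range(n)]
            col = rng.gamma(2, 30, size=n)
            m = int(rng.integers(1, n))
            S = set(rng.choice(genes, size=m, replace=False))
            if len(S) == n:
                continue
            tpm = ExpressionMatrix(pd.DataFrame({"s": col}, index=genes),
                                   unit="tpm")
            sc = ssgsea_score(tpm, GeneSetCollection({"S": S}),
                              alpha=0.25, normalize=False)
            expected = brute_force_ssgsea(col, genes, S, alpha=0.25)
            assert sc.loc["S", "s"] == pytest.approx(expected, abs=1e-12)

    def test_four_gene_hand_instance(self):
        tpm = ExpressionMatrix(pd.DataFrame(
            {"s": [8.0, 4.0, 2.0, 1.0]}, index=["a", "b", "c", "d"]),
            unit="tpm")
        sc = ssgsea_score(tpm, GeneSetCollection({"S": {"a"}}),
                          alpha=0.25, normalize=False)
        expected = brute_force_ssgsea([8.0, 4.0, 2.0, 1.0],
                                      ["a", "b", "c", "d"], {"a"}, 0.25)
        assert sc.loc["S", "s"] == pytest.approx(expected, abs=1e-12)

    def test_missing_genes_policy(self):
        tpm = ExpressionMatrix(pd.DataFrame(
            {"s": [1.0, 2.0, 3.0]}, index=["a", "b", "c"]), unit="tpm")
        # 2 of 3 genes present: allowed at the default 50% threshold
        gs_ok = GeneSetCollection({"S": {"a", "b", "zz"}})
        ssgsea_score(tpm, gs_ok)
        # 1 of 3 present: rejected
        with pytest.raises(DegenerateSetError, match="S"):
            ssgsea_score(tpm, GeneSetCollection({"S": {"a", "y", "z"}}))


class TestWelchFdr:
    def _scores(self, a, b):
        cols = {f"r{i}": [v] for i, v in enumerate(a)}
        cols |= {f"n{i}": [v] for i, v in enumerate(b)}
        scores = pd.DataFrame(cols, index=["P"])
        labels = pd.Series({**{f"r{i}": "R" for i in range(len(a))},
                            **{f"n{i}": "NR" for i in range(len(b))}})
        return scores, labels

    def test_identical_groups_are_null(self):
        scores, labels = self._scores([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = welch_fdr(scores, labels)
        assert res.loc["P", "t"] == pytest.approx(0.0)
        assert res.loc["P", "pvalue"] == pytest.approx(1.0)

    def test_power_on_shifted_groups(self):
        rng = np.random.default_rng(0)
        rejected = 0
        for _ in range(30):
            scores, labels = self._scores(rng.normal(1, 1, 50),
                                          rng.normal(0, 1, 50))
            if welch_fdr(scores, labels).loc["P", "pvalue"] < 1e-3:
                rejected += 1
        # power at this effect size (d=1, n=50/arm, alpha=1e-3) is ~95%
        assert rejected >= 26

    def test_bh_across_pathways(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(2, 20))
        b = rng.normal(0, 1, size=(2, 20))
        scores = pd.DataFrame(np.hstack([a, b]),
                              index=["P1", "P2"],
                              columns=[f"r{i}" for i in range(20)] +
                                      [f"n{i}" for i in range(20)])
        labels = pd.Series({**{f"r{i}": "R" for i in range(20)},
                            **{f"n{i}": "NR" for i in range(20)}})
        res = welch_fdr(scores, labels)
        from passig.diffexpr import bh_adjust
        np.testing.assert_allclose(res["fdr"], bh_adjust(res["pvalue"]))
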