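"""Evaluation statistics vs independent exact oracles."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plexus import (
    GRN,
    EvaluationConfig,
    GenomicFeatureSet,
    compare_grns,
    enrich_communities,
    f1_sets,
    fisher_significant_tfs,
    overlap_at_cutoffs,
    spearman_edge_weights,
)


def hypergeom_tail(a, b, c, d):
    """Exact one-sided p for table [[a,b],[c,d]]: P(X >= a) drawing a+b from
    a population of a+b+c+d with a+c successes.  Independent brute-force sum."""
    N = a + b + c + d
    K = a + c
    n = a + b
    denom = comb(N, n)
    return sum(
        comb(K, i) * comb(N - K, n - i) for i in range(a, min(K, n) + 1)
    ) / denom


class TestOverlapAtCutoffs:
    def test_counts_hits_at_increasing_cutoffs(self):
        ranking = [f"g{i}" for i in range(20)]
        gt = {"T": {"g0", "g3", "g8"}}  # hits at ranks 1, 4, 9
        cfg = EvaluationConfig(cutoffs=(3, 5, 10))
        res = overlap_at_cutoffs({"T": ranking}, gt, cfg)
        assert list(res) == [1.0, 2.0, 3.0]

    def test_tf_with_empty_truth_excluded_from_mean(self):
        ranking = [f"g{i}" for i in range(10)]
        gt = {"T1": {"g0"}, "T2": set()}
        res = overlap_at_cutoffs({"T1": ranking, "T2": ranking}, gt,
                                 EvaluationConfig(cutoffs=(3,)))
        assert res[3] == 1.0  # mean over T1 only

    def test_monotone_nondecreasing_in_cutoff(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(50)]
        rankings = {f"T{j}": list(rng.permutation(universe)) for j in range(5)}
        gt = {f"T{j}": set(rng.choice(universe, 8, replace=False)) for j in range(5)}
        res = overlap_at_cutoffs(rankings, gt, EvaluationConfig(cutoffs=(3, 5, 10, 20, 50)))
        assert (np.diff(res.values) >= 0).all()

    def test_random_ranking_matches_hypergeometric_expectation(self):
        """Mean overlap of permuted rankings ~ k*|gt|/|universe| (3 SE)."""
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(40)]
        gt = {"T": set(universe[:8])}
        k = 10
        vals = []
        for _ in range(1000):
            ranking = list(rng.permutation(universe))
            vals.append(
                overlap_at_cutoffs({"T": ranking}, gt, EvaluationConfig(cutoffs=(k,)))[k]
            )
        vals = np.array(vals)
        expected = k * 8 / 40
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expected) <= 3 * se

    def test_no_shared_tfs_raises(self):
        with pytest.raises(ValueError):
            overlap_at_cutoffs({"T1": ["g"]}, {"T2": {"g"}}, EvaluationConfig(cutoffs=(3,)))


class TestFisherSignificantTfs:
    def test_worked_table_matches_exact_tail_sum(self):
        """Table (4,6,16,74): 10 draws, 20 successes in 100."""
        universe = [f"g{i}" for i in range(100)]
        truth = set(universe[:4]) | set(universe[10:26])  # 20 truths, 4 in top 10
        ranking = universe[:4] + universe[30:36] + universe[4:10] + universe[10:30] \
            + universe[36:]
        # top-10 = 4 truths + 6 non-truths
        res = fisher_significant_tfs({"T": ranking}, {"T": truth}, k=10)
        assert res.pvalues["T"] == pytest.approx(hypergeom_tail(4, 6, 16, 74), abs=1e-12)

    def test_agreement_with_tail_sum_over_many_tables(self):
        """Implementation (scipy Fisher) vs brute-force tail sums, n <= 200."""
        rng = np.random.default_rng(2)
        from scipy.stats import fisher_exact

        for _ in range(300):
            a, b, c, d = rng.integers(0, 50, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
            assert p == pytest.approx(hypergeom_tail(int(a), int(b), int(c), int(d)),
                                      abs=1e-12)

    def test_perfect_prediction_is_counted(self):
        universe = [f"g{i}" for i in range(100)]
        gt = {"T": set(universe[:5])}
        res = fisher_significant_tfs({"T": universe}, gt, k=5)
        assert res.n_significant == 1
        assert res.pvalues["T"] == pytest.approx(1 / comb(100, 5), rel=1e-9)

    def test_empty_truth_excluded(self):
        universe = [f"g{i}" for i in range(10)]
        res = fisher_significant_tfs(
            {"T1": universe, "T2": universe}, {"T1": {"g0"}, "T2": set()}, k=3
        )
        assert set(res.pvalues.index) == {"T1"}

    def test_null_rankings_never_exceed_level(self):
        """Permuted rankings: significant count stays within the alpha bound."""
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(50)]
        gt = {f"T{j}": set(rng.choice(universe, 10, replace=False)) for j in range(10)}
        n_sig = 0
        n_reps = 200
        for _ in range(n_reps):
            rankings = {t: list(rng.permutation(universe)) for t in gt}
            n_sig += fisher_significant_tfs(rankings, gt, k=10).n_significant
        n_tests = n_reps * 10
        bound = 0.05 * n_tests + 3 * np.sqrt(n_tests * 0.05 * 0.95)
        assert n_sig <= bound


class TestF1:
    @pytest.mark.parametrize(
        "pred,truth,expected",
        [
            ({"a", "b", "c"}, {"a", "b", "c"}, 1.0),
            ({"a"}, {"b"}, 0.0),
            ({"a", "b", "c"}, {"b", "c", "d"}, 2 / 3),
            (set(), set(), 0.0),
        ],
    )
    def test_id_set_cases(self, pred, truth, expected):
        assert f1_sets(pred, truth) == pytest.approx(expected)

    @given(
        pred=st.sets(st.sampled_from("abcdefgh")),
        truth=st.sets(st.sampled_from("abcdefgh")),
    )
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_under_swap(self, pred, truth):
        assert f1_sets(pred, truth) == pytest.approx(f1_sets(truth, pred))

    def test_interval_overlap_matching(self):
        pred = GenomicFeatureSet.from_records(
            [("p1", "chr1", 100, 200, "."), ("p2", "chr1", 900, 1000, ".")]
        )
        truth = GenomicFeatureSet.from_records(
            [("t1", "chr1", 150, 260, "."), ("t2", "chr2", 100, 200, ".")]
        )
        # TP=1 (p1~t1), FP=1 (p2), FN=1 (t2) -> F1 = 2/4
        assert f1_sets(pred, truth) == pytest.approx(0.5)

    def test_adjacent_half_open_intervals_do_not_overlap(self):
        pred = GenomicFeatureSet.from_records([("p", "chr1", 100, 200, ".")])
        truth = GenomicFeatureSet.from_records([("t", "chr1", 200, 300, ".")])
        assert f1_sets(pred, truth) == 0.0


class TestEnrichCommunities:
    def test_raw_p_matches_tail_sum(self):
        """5-gene community, 4 in a 10-gene set, universe 50."""
        universe = [f"g{i}" for i in range(50)]
        comm = set(universe[:4]) | {universe[20]}
        gene_set = set(universe[:10])
        from scipy.stats import hypergeom

        p = hypergeom.sf(4 - 1, 50, 10, 5)
        brute = sum(
            comb(10, i) * comb(40, 5 - i) for i in range(4, 6)
        ) / comb(50, 5)
        assert p == pytest.approx(brute, abs=1e-12)
        res = enrich_communities(
            [comm], {"db": {"s1": gene_set}}, universe, alpha=0.05
        )
        assert res.loc["db", "n_enriched"] == (1 if brute < 0.05 else 0)

    def test_community_outside_universe_not_enriched(self):
        res = enrich_communities(
            [{"x1", "x2"}, {"g0", "g1", "g2"}],
            {"db": {"s": ["g0", "g1", "g2"]}},
            [f"g{i}" for i in range(30)],
        )
        assert res.loc["db", "n_enriched"] == 1  # only the in-universe community

    def test_percentage_reporting_format(self):
        universe = [f"g{i}" for i in range(40)]
        comms = [set(universe[i * 4 : (i + 1) * 4]) for i in range(10)]
        collections = {"db": {"s1": universe[0:4], "s2": universe[4:8]}}
        res = enrich_communities(comms, collections, universe)
        assert res.loc["db", "n_communities"] == 10
        assert res.loc["db", "pct_enriched"] == pytest.approx(
            10.0 * res.loc["db", "n_enriched"]
        )

    def test_namespaced_members_are_stripped(self):
        universe = [f"g{i}" for i in range(20)]
        res = enrich_communities(
            [{f"gene:{g}" for g in universe[:5]}],
            {"db": {"s": universe[:5]}},
            universe,
        )
        assert res.loc["db", "n_enriched"] == 1

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            enrich_communities([{"g"}], {"db": {}}, ["g"])


class TestCompareGrns:
    def grn(self, rows):
        return GRN(pd.DataFrame(rows, columns=["tf", "gene", "weight"]),
                   sorted({r[0] for r in rows}), sorted({r[1] for r in rows}))

    def test_identical_grns_give_one(self):
        g = self.grn([("T1", "g1", 0.5), ("T1", "g2", 0.2), ("T2", "g1", 0.1)])
        assert compare_grns(g, g) == pytest.approx(1.0)

    def test_reversed_weight_order_gives_minus_one(self):
        rows = [("T1", "g1", 0.5), ("T1", "g2", 0.2), ("T2", "g1", 0.1)]
        rev = [("T1", "g1", 0.1), ("T1", "g2", 0.2), ("T2", "g1", 0.5)]
        assert compare_grns(self.grn(rows), self.grn(rev)) == pytest.approx(-1.0)

    def test_missing_edges_get_zero_weight(self):
        g1 = self.grn([("T1", "g1", 1.0), ("T1", "g2", 0.5)])
        g2 = self.grn([("T1", "g1", 1.0)])
        rho = compare_grns(g1, g2)
        from scipy.stats import spearmanr

        assert rho == pytest.approx(spearmanr([1.0, 0.5], [1.0, 0.0]).statistic)

    def test_generic_edge_lists_supported(self):
        e1 = pd.DataFrame([("a", "b", 1.0), ("b", "c", 0.5)],
                          columns=["tf", "gene", "weight"])
        e2 = pd.DataFrame([("a", "b", 0.9), ("b", "c", 0.4)],
                          columns=["tf", "gene", "weight"])
        assert spearman_edge_weights(e1, e2) == pytest.approx(1.0)
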