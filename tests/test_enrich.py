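import math

import numpy as np
import pandas as pd
import pytest

from earlens.io import ExpressionMatrix, GeneSet, GeneSetCollection, SampleDescriptor
from earlens.enrich import (
    cluster_bias,
    fold_enrichment,
    genotype_contrast,
    hypergeom_tail,
    rank_set_test,
    set_overrepresentation,
    zeb1_target_candidates,
)


def _enumerated_tail(k, K, n, N):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


class TestHypergeomTail:
    def test_hand_example(self):
        assert hypergeom_tail(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)

    def test_k_zero_is_one(self):
        assert hypergeom_tail(0, 3, 4, 10) == 1.0

    def test_enumeration_oracle_small_universe(self):
        for N in (5, 9, 12):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        expect = _enumerated_tail(k, K, n, N)
                        got = hypergeom_tail(k, K, n, N)
                        assert got == pytest.approx(expect, rel=1e-10, abs=1e-300)

    def test_symmetric_in_K_n_swap(self):
        for (k, K, n, N) in [(2, 5, 7, 20), (1, 3, 9, 12), (4, 6, 8, 30)]:
            assert hypergeom_tail(k, K, n, N) == pytest.approx(
                hypergeom_tail(k, n, K, N), rel=1e-12)

    def test_inconsistent_arguments_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(6, 5, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_tail(1, 11, 5, 10)


class TestFoldEnrichment:
    def test_deafness_gene_worked_example(self):
        """24 of 44 disease genes differential vs a 22% background rate."""
        assert fold_enrichment(24, 44, 0.22) == pytest.approx(2.5, abs=0.05)
        assert round(fold_enrichment(24, 44, 0.22), 1) == 2.5

    def test_edge_values(self):
        assert fold_enrichment(0, 10, 0.5) == 0.0
        assert fold_enrichment(5, 10, 0.5) == pytest.approx(1.0)


class TestSetOverrepresentation:
    def _fixture(self):
        universe = [f"g{i}" for i in range(40)]
        ann = GeneSetCollection([
            GeneSet("hit", "", tuple(universe[:10])),
            GeneSet("miss", "", tuple(universe[30:])),
        ], universe=universe)
        return universe, ann

    def test_query_equal_to_annotation_is_minimal_p(self):
        universe, ann = self._fixture()
        q = GeneSet("q", "", tuple(universe[:10]))
        table = set_overrepresentation(q, ann)
        assert table.index[0] == "hit"
        assert table.loc["hit", "p_hyper"] < table.loc["miss", "p_hyper"]
        assert table.loc["miss", "k"] == 0 and table.loc["miss", "fold"] == 0.0

    def test_p_matches_direct_tail_call(self):
        universe, ann = self._fixture()
        q = GeneSet("q", "", tuple(universe[5:20]))
        table = set_overrepresentation(q, ann)
        for name in ("hit", "miss"):
            row = table.loc[name]
            assert row["p_hyper"] == pytest.approx(
                hypergeom_tail(int(row["k"]), int(row["K"]), int(row["n"]), int(row["N"])),
                rel=1e-12)


class TestClusterBias:
    def _clusters(self):
        from earlens.signatures import ClusterResult
        genes = [f"g{i}" for i in range(60)]
        labels = pd.Series([1] * 20 + [2] * 20 + [3] * 20, index=genes)
        return ClusterResult(assignments=labels, patterns=None, pattern_sd=None,
                             k=3, seed=0, restarts=1, inertia=0.0)

    def test_all_specials_in_focal_clusters(self):
        clusters = self._clusters()
        special = GeneSet("s", "", tuple(f"g{i}" for i in range(10)))
        res = cluster_bias(special, clusters, focal_clusters=[1])
        assert res.k == 10
        assert res.p_hyper == pytest.approx(
            hypergeom_tail(10, 20, 10, 60), rel=1e-12)

    def test_equals_overrepresentation_with_focal_union(self):
        clusters = self._clusters()
        special = GeneSet("s", "", tuple(f"g{i}" for i in range(5, 35)))
        res = cluster_bias(special, clusters, focal_clusters=[1, 2])
        focal = GeneSetCollection(
            [GeneSet("focal", "", tuple(f"g{i}" for i in range(40)))],
            universe=[f"g{i}" for i in range(60)])
        table = set_overrepresentation(special, focal)
        assert res.p_hyper == pytest.approx(table.loc["focal", "p_hyper"], rel=1e-12)


def _single_array(values, sid, genotype="wt"):
    genes = [f"g{i}" for i in range(len(values))]
    s = SampleDescriptor(sid, "mixed", "cochlea", 1, genotype=genotype,
                         compartment="CD326neg")
    return ExpressionMatrix(
        values=pd.DataFrame({sid: values}, index=genes),
        samples=[s], probe_to_gene={g: g for g in genes}, scale="linear")


class TestGenotypeContrast:
    def test_identical_arrays_give_zero(self):
        x = np.array([1.0, 4.0, 16.0])
        fc = genotype_contrast(_single_array(x, "m", "Tw_hom"), _single_array(x, "c"))
        assert np.allclose(fc.to_numpy(), 0.0, atol=1e-12)

    def test_doubling_without_joint_normalization_is_one(self):
        x = np.array([1.0, 4.0, 16.0, 64.0])
        fc = genotype_contrast(_single_array(2 * x, "m", "Tw_hom"),
                               _single_array(x, "c"), joint_normalize=False)
        # log2(2x+1) - log2(x+1) -> close to 1 for large x
        assert fc.to_numpy()[-1] == pytest.approx(1.0, abs=0.02)

    def test_matches_subtraction_oracle(self):
        rng = np.random.default_rng(40)
        a, b = rng.uniform(1, 100, 50), rng.uniform(1, 100, 50)
        fc = genotype_contrast(_single_array(a, "m", "Tw_hom"), _single_array(b, "c"),
                               joint_normalize=False)
        assert np.allclose(fc.to_numpy(), np.log2(a + 1) - np.log2(b + 1), atol=1e-12)

    def test_mismatched_index_rejected(self):
        m = _single_array(np.ones(3), "m", "Tw_hom")
        c = _single_array(np.ones(4), "c")
        with pytest.raises(ValueError, match="index"):
            genotype_contrast(m, c)


class TestRankSetTest:
    def _fc(self, n=500, seed=41):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])

    def test_markers_at_top_give_minimal_p_and_barcode(self):
        fc = self._fc()
        ordered = fc.sort_values(ascending=False)
        markers = GeneSet("m", "", tuple(ordered.index[:30]))
        res = rank_set_test(fc, markers)
        assert res.barcode == list(range(1, 31))
        assert res.direction == "+"
        # complete separation: smallest attainable two-sided asymptotic p
        shuffled = rank_set_test(fc, GeneSet("r", "", tuple(fc.index[::7][:30])))
        assert res.p < shuffled.p

    def test_null_p_not_extreme(self):
        fc = self._fc(seed=42)
        rng = np.random.default_rng(43)
        ps = []
        for _ in range(50):
            members = rng.choice(fc.index, size=40, replace=False)
            ps.append(rank_set_test(fc, GeneSet("m", "", tuple(members))).p)
        ps = np.array(ps)
        assert (ps < 0.01).mean() <= 0.1
        assert ps.min() > 1e-5

    def test_monotone_transform_invariance(self):
        fc = self._fc(seed=44)
        markers = GeneSet("m", "", tuple(fc.index[:40]))
        a = rank_set_test(fc, markers)
        b = rank_set_test(pd.Series(np.exp(fc), index=fc.index), markers)
        assert a.p == pytest.approx(b.p, rel=1e-9)
        assert a.barcode == b.barcode

    def test_small_overlap_untested(self):
        fc = self._fc()
        res = rank_set_test(fc, GeneSet("m", "", ("g0", "g1")))
        assert not res.tested and res.p is None


class TestZebCandidates:
    def test_inclusion_rules(self):
        fc = pd.Series({"up_hit": 2.0, "up_nohit": 2.0, "down_hit": -1.0,
                        "weak_hit": 0.5, "other": 3.0})
        markers = GeneSet("epi", "", ("up_hit", "up_nohit", "down_hit", "weak_hit"))
        table = zeb1_target_candidates(fc, markers, {"up_hit", "down_hit", "weak_hit", "other"})
        assert table["gene"].tolist() == ["up_hit"]

    def test_sorted_by_fold_change(self):
        fc = pd.Series({"a": 1.2, "b": 3.0, "c": 2.1})
        markers = GeneSet("epi", "", ("a", "b", "c"))
        table = zeb1_target_candidates(fc, markers, {"a", "b", "c"})
        assert table["gene"].tolist() == ["b", "c", "a"]
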