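import numpy as np
import pandas as pd
import pytest

from earlens.io import ExpressionMatrix, SampleDescriptor
from earlens.signatures import (
    bh_fdr,
    define_markers,
    hierarchical_samples,
    kmeans_genes,
    standardize_rows,
    two_way_anova,
)
from tests.conftest import make_profile


def _factorial_matrix(values, a=2, b=2, r=2, scale="log2"):
    """values: genes x (a*b*r) laid out cell-major then organ then replicate."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = []
    cts = [f"ct{i}" for i in range(a)]
    organs = [f"org{j}" for j in range(b)]
    for ct in cts:
        for org in organs:
            for rep in range(1, r + 1):
                samples.append(SampleDescriptor(f"{ct}_{org}_{rep}", ct, org, rep))
    probes = [f"g{i}" for i in range(values.shape[0])]
    vdf = pd.DataFrame(values, index=probes, columns=[s.sample_id for s in samples])
    return ExpressionMatrix(values=vdf, samples=samples,
                            probe_to_gene={p: p for p in probes}, scale=scale)


class TestTwoWayAnova:
    def test_flat_gene_is_degenerate_with_p_one(self):
        m = _factorial_matrix(np.full((1, 8), 3.0))
        res = two_way_anova(m).table.iloc[0]
        assert res["degenerate"]
        assert res["p_cell"] == 1.0 and res["p_organ"] == 1.0
        assert not res["is_differential"]

    def test_pure_cell_effect_beats_organ(self):
        # cell A around 1, cell B around 3, tiny replicate jitter for variance
        y = np.array([[1, 1.01, 1, 1.01, 3, 3.01, 3, 3.01]])
        res = two_way_anova(_factorial_matrix(y)).table.iloc[0]
        assert res["p_cell"] < res["p_organ"]
        assert res["F_organ"] == pytest.approx(0.0, abs=1e-6)

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        rng = np.random.default_rng(12)
        a, b, r = 4, 2, 3
        y = rng.normal(size=(5, a * b * r))
        m = _factorial_matrix(y, a=a, b=b, r=r)
        res = two_way_anova(m).table
        frame = m.sample_frame()
        for gi in range(5):
            df = frame.copy()
            df["y"] = m.values.iloc[gi].to_numpy()
            fit = ols("y ~ C(cell_type) * C(organ)", data=df).fit()
            tbl = sm.stats.anova_lm(fit, typ=2)
            assert res.iloc[gi]["F_cell"] == pytest.approx(
                tbl.loc["C(cell_type)", "F"], abs=1e-8, rel=1e-8)
            assert res.iloc[gi]["F_organ"] == pytest.approx(
                tbl.loc["C(organ)", "F"], abs=1e-8, rel=1e-8)
            assert res.iloc[gi]["F_interaction"] == pytest.approx(
                tbl.loc["C(cell_type):C(organ)", "F"], abs=1e-8, rel=1e-8)
            assert res.iloc[gi]["p_cell"] == pytest.approx(
                tbl.loc["C(cell_type)", "PR(>F)"], rel=1e-8)

    def test_unbalanced_design_rejected(self):
        m = _factorial_matrix(np.ones((1, 8)))
        sub = m.subset_samples(m.sample_ids[1:])
        with pytest.raises(ValueError, match="balanced"):
            two_way_anova(sub)


class TestBH:
    def test_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_and_dominance(self):
        assert np.allclose(bh_fdr([1.0, 1.0]), [1.0, 1.0])
        rng = np.random.default_rng(13)
        p = rng.uniform(size=100)
        assert (bh_fdr(p) >= p - 1e-12).all()


class TestDendrogram:
    def test_duplicated_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(14)
        base = rng.normal(size=20)
        other = rng.normal(size=20)
        y = np.column_stack([base, base, other, other + rng.normal(0, 0.3, 20)])
        m = _factorial_matrix(y.reshape(20, 4).T.reshape(20, 4) * 0 + y, a=2, b=2, r=1)
        # need >=2 reps only for anova; dendrogram takes any >=3 samples
        d = hierarchical_samples(m)
        first_merge = d.linkage[0]
        assert first_merge[2] == pytest.approx(0.0, abs=1e-12)
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}

    def test_heights_non_decreasing_on_real_data(self, processed):
        d = hierarchical_samples(processed["gene_log2"])
        h = d.merge_heights()
        assert (np.diff(h) >= -1e-12).all()

    def test_constant_sample_rejected_under_correlation(self):
        y = np.column_stack([np.full(10, 5.0), np.arange(10.0), np.arange(10.0) ** 2])
        m = _factorial_matrix(y.T.reshape(3, 10).T * 0 + y, a=3, b=1, r=1)
        with pytest.raises(ValueError, match="[Ee]uclidean"):
            hierarchical_samples(m)


class TestStandardizeRows:
    def test_hand_example_population_sd(self):
        prof = make_profile(np.array([[1.0, 2.0, 3.0]]))
        out = standardize_rows(prof).means.to_numpy()[0]
        assert np.allclose(out, [-1.224744871, 0.0, 1.224744871], atol=1e-6)

    def test_unit_sd_and_constant_rows_dropped(self):
        x = np.vstack([np.arange(8.0), np.full(8, 2.0), np.random.default_rng(0).normal(size=8)])
        with pytest.warns(UserWarning, match="constant"):
            out = standardize_rows(make_profile(x))
        z = out.means.to_numpy()
        assert z.shape[0] == 2
        assert np.allclose(z.std(axis=1), 1.0, atol=1e-12)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)


class TestKMeans:
    def _archetypes(self, n_per=20, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        pats = np.array([
            [1, 1, -1, -1, 1, 1, -1, -1],
            [-1, -1, 1, 1, -1, -1, 1, 1],
            [1, -1, 1, -1, 1, -1, 1, -1],
        ], dtype=float)
        rows, labels = [], []
        for ci, p in enumerate(pats):
            for _ in range(n_per):
                rows.append(p + rng.normal(0, noise, 8))
                labels.append(ci)
        x = np.array(rows)
        x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        return make_profile(x), np.array(labels)

    def test_exact_archetypes_partition_with_zero_inertia(self):
        prof, labels = self._archetypes(noise=0.0)
        res = kmeans_genes(prof, k=3, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-9)
        for ci in range(3):
            assigned = res.assignments.to_numpy()[labels == ci]
            assert len(set(assigned)) == 1

    def test_fixed_seed_reproducible(self):
        prof, _ = self._archetypes(noise=0.3, seed=5)
        a = kmeans_genes(prof, k=3, seed=42)
        b = kmeans_genes(prof, k=3, seed=42)
        assert a.assignments.equals(b.assignments)
        assert a.inertia == b.inertia

    def test_recovers_planted_marker_patterns(self, processed, default_dataset):
        from sklearn.metrics import adjusted_rand_score
        truth = default_dataset.truth.planted_markers
        genes, labels = [], []
        prof = processed["profile"]
        for ci, ct in enumerate(sorted(truth)):
            for g in sorted(truth[ct]):
                if g in prof.means.index:
                    genes.append(g)
                    labels.append(ci)
        std = standardize_rows(make_profile(prof.means.loc[genes].to_numpy(), genes=genes))
        res = kmeans_genes(std, k=4, seed=0)
        ari = adjusted_rand_score(labels, res.assignments.loc[genes].to_numpy())
        assert ari >= 0.9

    def test_k_larger_than_distinct_rows_rejected(self):
        prof = make_profile(np.tile([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0], (5, 1)))
        with pytest.raises(ValueError, match="distinct"):
            kmeans_genes(prof, k=3, seed=0)


class TestMarkerRule:
    def _linear_matrix(self, values, a=2, r=3):
        return _factorial_matrix(values, a=a, b=1, r=r, scale="linear")

    def test_inclusive_boundary_assigns_at_exactly_threshold(self):
        # in-type min 30 == 1.5 * out-type max 20 -> assigned
        y = np.array([[30, 31, 32, 18, 19, 20]])
        res = define_markers(self._linear_matrix(y))
        assert res.table.iloc[0]["cell_type"] == "ct0"
        assert res.table.iloc[0]["margin"] == pytest.approx(1.5)

    def test_below_threshold_not_assigned(self):
        y = np.array([[29, 31, 32, 18, 19, 20]])
        res = define_markers(self._linear_matrix(y))
        assert pd.isna(res.table.iloc[0]["cell_type"])

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(15)
        for trial in range(10):
            y = rng.uniform(1, 40, size=(500, 12))
            m = _factorial_matrix(y, a=4, b=1, r=3, scale="linear")
            res = define_markers(m)
            frame = m.sample_frame()
            cts = sorted(frame["cell_type"].unique())
            for gi in range(500):
                expect = None
                for ct in cts:
                    ins = y[gi, [i for i, s in enumerate(frame.index)
                                 if frame.loc[s, "cell_type"] == ct]]
                    outs = y[gi, [i for i, s in enumerate(frame.index)
                                  if frame.loc[s, "cell_type"] != ct]]
                    if ins.min() >= 1.5 * outs.max():
                        expect = ct
                got = res.table.iloc[gi]["cell_type"]
                assert (got if pd.notna(got) else None) == expect

    def test_sets_disjoint_and_scale_invariant(self, processed):
        res = define_markers(processed["gene_linear"])
        sets = res.as_dict()
        names = list(sets)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                assert not (sets[names[i]] & sets[names[j]])
        scaled = processed["gene_linear"]
        scaled = ExpressionMatrix(values=scaled.values * 1000.0,
                                  samples=list(scaled.samples),
                                  probe_to_gene=scaled.probe_to_gene,
                                  scale="linear")
        res2 = define_markers(scaled)
        assert res2.as_dict() == sets

    def test_log_scale_rejected(self, processed):
        with pytest.raises(ValueError, match="linear"):
            define_markers(processed["gene_log2"])
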