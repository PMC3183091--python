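import itertools
import math

import numpy as np
import pytest

from earlens.io import GeneSet, GeneSetCollection, PromoterSet, reverse_complement
from earlens.motifs import (
    build_pwm,
    canonical,
    cross_check_factor_expression,
    discover,
    find_sites,
    scan_kmers,
)
from tests.conftest import make_profile


def _promoters(seqs, length=None):
    length = length or max(len(s) for s in seqs.values())
    clipped = frozenset(g for g, s in seqs.items() if len(s) < length)
    return PromoterSet(sequences=seqs, upstream=length, downstream=0, clipped=clipped)


class TestScanKmers:
    def test_hand_hypergeometric_example(self):
        """Word in 5 of 10 promoters; target = exactly those 5."""
        rng = np.random.default_rng(30)
        word = "ACGTACGT"
        seqs = {}
        for i in range(10):
            s = "".join(rng.choice(list("ACGT"), size=50))
            while word in s or reverse_complement(word) in s:
                s = "".join(rng.choice(list("ACGT"), size=50))
            if i < 5:
                s = word + s[8:]
            seqs[f"g{i}"] = s
        uni = _promoters(seqs)
        tgt = uni.subset([f"g{i}" for i in range(5)])
        stats = scan_kmers(tgt, uni, k=8)
        top = stats[0]
        assert top.kmer == canonical(word)
        assert (top.k_t, top.K, top.n, top.N) == (5, 5, 5, 10)
        assert top.p_hyper == pytest.approx(1 / math.comb(10, 5), rel=1e-9)

    def test_matches_brute_force_on_random_universes(self):
        rng = np.random.default_rng(31)
        for trial in range(50):
            n_prom = int(rng.integers(5, 31))
            seqs = {f"g{i}": "".join(rng.choice(list("ACGTN"), size=40,
                                                p=[0.24, 0.24, 0.24, 0.24, 0.04]))
                    for i in range(n_prom)}
            uni = _promoters(seqs)
            tgt_genes = sorted(rng.choice(list(seqs), size=n_prom // 2, replace=False))
            stats = scan_kmers(uni.subset(tgt_genes), uni, k=4)
            # brute force: presence of every canonical 4-mer per promoter
            def present(seq, kmer):
                rc = reverse_complement(kmer)
                for off in range(len(seq) - 3):
                    w = seq[off:off + 4]
                    if "N" in w:
                        continue
                    if w == kmer or w == rc:
                        return True
                return False
            counts = {}
            for kmer in ("".join(t) for t in itertools.product("ACGT", repeat=4)):
                c = canonical(kmer)
                if c in counts:
                    continue
                K = sum(present(s, c) for s in seqs.values())
                kt = sum(present(seqs[g], c) for g in tgt_genes)
                if K:
                    counts[c] = (K, kt)
            got = {s.kmer: (s.K, s.k_t) for s in stats}
            assert got == counts

    def test_word_and_revcomp_merge_into_one_canonical_entry(self):
        seqs = {"g0": "AAAACCCC" + "G" * 20,    # contains AAAACCCC
                "g1": "GGGGTTTT" + "A" * 20,    # contains its reverse complement
                "g2": "ACACACAC" + "T" * 20}
        uni = _promoters(seqs)
        stats = scan_kmers(uni.subset(["g0", "g1"]), uni, k=8)
        merged = [s for s in stats if s.kmer == "AAAACCCC"]
        assert len(merged) == 1 and merged[0].K == 2 and merged[0].k_t == 2
        assert not any(s.kmer == "GGGGTTTT" for s in stats)

    def test_duplicated_instance_in_one_promoter_counts_once(self):
        word = "ACGTTGCA"
        base = {"g0": word + "A" * 30, "g1": "C" * 38, "g2": "T" * 38}
        dup = {"g0": word + word + "A" * 22, "g1": "C" * 38, "g2": "T" * 38}
        s1 = scan_kmers(_promoters(base).subset(["g0"]), _promoters(base), k=8)
        s2 = scan_kmers(_promoters(dup).subset(["g0"]), _promoters(dup), k=8)
        t1 = [s for s in s1 if s.kmer == canonical(word)][0]
        t2 = [s for s in s2 if s.kmer == canonical(word)][0]
        assert (t1.K, t1.k_t, t1.p_hyper) == (t2.K, t2.k_t, t2.p_hyper)

    def test_parameter_validation(self):
        uni = _promoters({"g0": "ACGT" * 10})
        with pytest.raises(ValueError, match="k"):
            scan_kmers(uni, uni, k=3)
        with pytest.raises(ValueError, match="empty"):
            scan_kmers(_promoters({"g0": "ACGT" * 10}).subset([]), uni, k=8)


class TestBuildPWM:
    def test_identical_sites_closed_form(self):
        word = "ACGTACGT"
        seqs = {f"g{i}": word + "A" * 20 for i in range(6)}
        res = build_pwm(word, _promoters(seqs), pseudocount=0.5)
        c = len(res.sites)
        assert c == 6
        expect_max = (c + 0.5) / (c + 2.0)
        for pos, base in enumerate(word):
            col = res.pwm[pos]
            assert col.max() == pytest.approx(expect_max, rel=1e-9)
        assert np.allclose(res.pwm.sum(axis=1), 1.0, atol=1e-9)

    def test_revcomp_hits_stacked_in_seed_orientation(self):
        word = "AACCGGTT"  # not palindromic? revcomp = AACCGGTT -> palindromic, pick another
        word = "AAACCGGG"
        rc = reverse_complement(word)
        seqs = {"g0": word + "A" * 20, "g1": rc + "A" * 20,
                "g2": word + "C" * 20, "g3": rc + "C" * 20, "g4": word + "T" * 20}
        res = build_pwm(word, _promoters(seqs))
        assert len(res.sites) == 5
        assert res.consensus == canonical(word)

    def test_too_few_sites_refused(self):
        seqs = {"g0": "ACGTACGT" + "A" * 20, "g1": "C" * 28}
        res = build_pwm("ACGTACGT", _promoters(seqs))
        assert res.pwm is None and len(res.sites) == 1

    def test_information_content_extremes(self):
        word = "ACGTACGT"
        seqs = {f"g{i}": word + "G" * 20 for i in range(20)}
        res = build_pwm(word, _promoters(seqs), pseudocount=0.0)
        assert np.allclose(res.information_content, 2.0, atol=1e-9)
        uniform = np.full((1, 4), 0.25)
        ent = -(uniform * np.log2(uniform)).sum()
        assert 2.0 - ent == pytest.approx(0.0, abs=1e-12)


class TestDiscover:
    def _planted_universe(self, seed=32, n_target=60, n_bg=400, length=300,
                          f_t=0.5, f_b=0.02, consensus="CACCTGTC"):
        rng = np.random.default_rng(seed)
        seqs, targets = {}, []
        k = len(consensus)
        for i in range(n_target + n_bg):
            g = f"g{i:04d}"
            s = "".join(rng.choice(list("ACGT"), size=length))
            rate = f_t if i < n_target else f_b
            if rng.random() < rate:
                off = int(rng.integers(0, length - k))
                word = consensus if rng.random() < 0.5 else reverse_complement(consensus)
                s = s[:off] + word + s[off + k:]
            seqs[g] = s
            if i < n_target:
                targets.append(g)
        return _promoters(seqs), targets

    def test_planted_motif_ranked_first_only_in_planted_set(self):
        uni, targets = self._planted_universe()
        other = [g for g in uni.gene_ids if g not in set(targets)][:60]
        coll = GeneSetCollection([
            GeneSet("planted", "", tuple(targets)),
            GeneSet("unplanted", "", tuple(other)),
        ], universe=uni.gene_ids)
        res = discover(coll, uni, k_range=(8,), alpha=1e-4)
        top = res["planted"][0]
        assert top.seed.kmer == canonical("CACCTGTC")
        assert top.significant and top.seed.p_corrected < 1e-4
        assert all(not m.significant for m in res["unplanted"])
        assert len(res["unplanted"]) == 1  # best seed still reported

    def test_deterministic(self):
        uni, targets = self._planted_universe(seed=33)
        coll = GeneSetCollection([GeneSet("t", "", tuple(targets))],
                                 universe=uni.gene_ids)
        a = discover(coll, uni, k_range=(7, 8))
        b = discover(coll, uni, k_range=(7, 8))
        assert [(m.seed.kmer, m.seed.p_corrected) for m in a["t"]] == \
               [(m.seed.kmer, m.seed.p_corrected) for m in b["t"]]

    def test_high_n_promoters_dropped_with_warning(self):
        seqs = {"g0": "N" * 300, "g1": "ACGT" * 75, "g2": "AGCT" * 75}
        uni = _promoters(seqs)
        with pytest.warns(UserWarning, match="N content"):
            scan_kmers(uni.subset(["g1"]), uni, k=8)


class TestCrossCheck:
    def test_repressor_consistency_and_missing_factor(self):
        rng = np.random.default_rng(34)
        x = rng.normal(0, 0.05, size=(50, 8))
        x[:20, 0] += 2.0   # motif-hit genes high in condition 0
        x[20, 0] -= 2.0    # factor depleted in condition 0
        prof = make_profile(x)
        hits = set(prof.gene_ids[:20])
        table = cross_check_factor_expression(hits, [prof.gene_ids[20], "absent_gene"],
                                              prof, mode="repressor")
        assert len(table) == 2 * 8
        row = table[(table["factor"] == prof.gene_ids[20])
                    & (table["cell_type"] == "sensory")
                    & (table["organ"] == "cochlea")].iloc[0]
        assert row["consistent"]
        assert table[table["factor"] == "absent_gene"]["absent"].all()
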