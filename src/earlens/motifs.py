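"""De novo promoter motif enrichment by canonical k-mer scanning.

A k-mer and its reverse complement are collapsed into one canonical word
(the lexicographic minimum), so scanning is strand-agnostic.  For each
canonical k-mer the score is the hypergeometric upper tail of its
promoter-presence count in a target set (e.g. the sensory marker genes)
against the background universe of all expressed-gene promoters; a promoter
counts once however many instances it carries.  Bonferroni correction runs
over the canonical k-mers actually observed in the universe — the heavy
multiplicity of a discovery-style scan argues for family-wise control.
Significant seeds are expanded into position weight matrices from their
exact hit sites.

Promoters with more than 20% N content are dropped before scanning, and any
window containing an N is skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ConditionProfile, GeneSetCollection, PromoterSet, reverse_complement

_BASES = "ACGT"
_CODE = {c: i for i, c in enumerate(_BASES)}
MAX_N_FRACTION = 0.20


@dataclass
class KmerStat:
    kmer: str            # canonical form
    K: int               # universe promoters containing it
    k_t: int             # target promoters containing it
    N: int               # universe size
    n: int               # target size
    p_hyper: float
    p_corrected: float
    width: int = field(init=False)

    def __post_init__(self):
        if not (0 <= self.k_t <= min(self.K, self.n)):
            raise ValueError(f"inconsistent counts for {self.kmer}")
        self.width = len(self.kmer)


@dataclass
class MotifResult:
    seed: KmerStat
    pwm: np.ndarray | None                     # width x 4 probabilities
    sites: list[tuple[str, int, str]]          # (gene, offset, strand)
    information_content: np.ndarray | None     # bits per position
    significant: bool = True
    set_name: str | None = None

    @property
    def consensus(self) -> str:
        if self.pwm is None:
            return self.seed.kmer
        return "".join(_BASES[i] for i in self.pwm.argmax(axis=1))

    def to_meme(self, name: str | None = None) -> str:
        """Minimal MEME text block for this motif."""
        if self.pwm is None:
            raise ValueError("seed-only result has no PWM")
        lines = [f"MOTIF {name or self.seed.kmer}",
                 f"letter-probability matrix: alength= 4 w= {self.pwm.shape[0]} "
                 f"nsites= {len(self.sites)} E= {self.seed.p_corrected:.3g}"]
        for row in self.pwm:
            lines.append(" " + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _encode(seq: str) -> np.ndarray:
    """Map ACGTN -> 0..3, 4; returns int8 array."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def _promoter_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Sorted unique canonical k-mer codes present in one promoter.

    Windows containing N are skipped.  The canonical code is
    min(code, revcomp code) under the base-4 encoding, which coincides with
    the lexicographic rule because A<C<G<T in both orderings.
    """
    codes = _encode(seq)
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win != 4).all(axis=1)
    if not valid.any():
        return np.empty(0, dtype=np.int64)
    win = win[valid].astype(np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win @ powers
    rev = (3 - win)[:, ::-1] @ powers
    return np.unique(np.minimum(fwd, rev))


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def _usable(promoters: PromoterSet) -> list[str]:
    keep, dropped = [], []
    for g, s in promoters.sequences.items():
        if s and s.count("N") / len(s) > MAX_N_FRACTION:
            dropped.append(g)
        else:
            keep.append(g)
    if dropped:
        warnings.warn(f"dropping {len(dropped)} promoters with >20% N content")
    return keep


def scan_kmers(targets: PromoterSet, universe: PromoterSet, k: int = 8) -> list[KmerStat]:
    """Rank canonical k-mers by hypergeometric presence enrichment.

    ``targets`` must be a subset of ``universe``.  Returns KmerStats sorted
    by corrected then raw p (ties by k-mer string, so output is
    deterministic).
    """
    if not 4 <= k <= 12:
        raise ValueError(f"k must be in 4..12, got {k}")
    if len(targets) == 0:
        raise ValueError("empty target promoter set")
    if not set(targets.gene_ids) <= set(universe.gene_ids):
        raise ValueError("target promoters must be a subset of the universe")

    uni_genes = _usable(universe)
    target_ids = set(targets.gene_ids) & set(uni_genes)
    per_promoter = {g: _promoter_kmer_codes(universe[g], k) for g in uni_genes}

    all_codes = np.concatenate([per_promoter[g] for g in uni_genes]) \
        if uni_genes else np.empty(0, dtype=np.int64)
    codes, K_counts = np.unique(all_codes, return_counts=True)
    tgt_codes_list = [per_promoter[g] for g in uni_genes if g in target_ids]
    tgt_all = np.concatenate(tgt_codes_list) if tgt_codes_list else np.empty(0, dtype=np.int64)
    tgt_codes, kt_counts = np.unique(tgt_all, return_counts=True)
    kt_map = np.zeros(codes.size, dtype=np.int64)
    kt_map[np.searchsorted(codes, tgt_codes)] = kt_counts

    N, n = len(uni_genes), len(target_ids)
    n_tests = codes.size
    p_hyper = stats.hypergeom.sf(kt_map - 1, N, K_counts, n)
    p_corr = np.minimum(p_hyper * n_tests, 1.0)
    out = [
        KmerStat(_decode(int(c), k), int(K), int(kt), N, n, float(ph), float(pc))
        for c, K, kt, ph, pc in zip(codes, K_counts, kt_map, p_hyper, p_corr)
    ]
    out.sort(key=lambda s: (s.p_corrected, s.p_hyper, s.kmer))
    return out


def find_sites(seed: str, promoters: PromoterSet,
               genes: list[str] | None = None) -> list[tuple[str, int, str]]:
    """Exact occurrences of a canonical seed (both strands) per promoter."""
    rc = reverse_complement(seed)
    words = {seed: "+"} if seed == rc else {seed: "+", rc: "-"}
    sites = []
    for g in (genes if genes is not None else promoters.gene_ids):
        seq = promoters[g]
        for word, strand in words.items():
            start = seq.find(word)
            while start != -1:
                sites.append((g, start, strand))
                start = seq.find(word, start + 1)
    return sites


def build_pwm(seed: str, targets: PromoterSet, pseudocount: float = 0.5,
              stat: KmerStat | None = None, min_sites: int = 5) -> MotifResult:
    """Stack exact seed hits into a PWM with a pseudocount.

    Reverse-complement hits are reverse-complemented before stacking so all
    sites read in the seed orientation.  With fewer than ``min_sites`` hits
    the PWM is refused and a seed-only result returned.
    """
    seed = canonical(seed)
    sites = find_sites(seed, targets)
    if stat is None:
        stat = KmerStat(seed, len(sites), len(sites), max(len(targets), 1),
                        max(len(targets), 1), 1.0, 1.0)
    if len(sites) < min_sites:
        return MotifResult(seed=stat, pwm=None, sites=sites,
                           information_content=None)
    k = len(seed)
    counts = np.zeros((k, 4))
    for g, off, strand in sites:
        word = targets[g][off:off + k]
        if strand == "-":
            word = reverse_complement(word)
        for pos, base in enumerate(word):
            counts[pos, _CODE[base]] += 1
    pwm = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pwm > 0, pwm * np.log2(pwm), 0.0)  # 0*log0 := 0
    ent = -plogp.sum(axis=1)
    ic = 2.0 - ent
    return MotifResult(seed=stat, pwm=pwm, sites=sites, information_content=ic)


def discover(marker_sets: GeneSetCollection, promoters: PromoterSet,
             k_range: tuple[int, ...] = (7, 8, 9),
             alpha: float = 1e-4, pseudocount: float = 0.5) -> dict[str, list[MotifResult]]:
    """Per marker set: scan every k in ``k_range``, pool, re-correct across
    the pooled tests and return motifs below ``alpha`` — always including the
    single best seed, flagged non-significant if above alpha."""
    results: dict[str, list[MotifResult]] = {}
    usable = set(_usable(promoters))
    for gs in marker_sets:
        target_genes = [g for g in gs.members if g in usable]
        if not target_genes:
            results[gs.name] = []
            continue
        target_prom = promoters.subset(target_genes)
        pooled: list[KmerStat] = []
        total_tests = 0
        per_k: list[list[KmerStat]] = []
        for k in k_range:
            stats_k = scan_kmers(target_prom, promoters, k=k)
            per_k.append(stats_k)
            total_tests += len(stats_k)
        for stats_k in per_k:
            for s in stats_k:
                s.p_corrected = min(s.p_hyper * total_tests, 1.0)
                pooled.append(s)
        pooled.sort(key=lambda s: (s.p_corrected, s.p_hyper, s.kmer))
        chosen = [s for s in pooled if s.p_corrected < alpha]
        if not chosen and pooled:
            chosen = [pooled[0]]
        motifs = []
        for s in chosen:
            mr = build_pwm(s.kmer, target_prom, pseudocount=pseudocount, stat=s)
            mr.significant = s.p_corrected < alpha
            mr.set_name = gs.name
            motifs.append(mr)
        results[gs.name] = motifs
    return results


def cross_check_factor_expression(motif_hit_genes: set[str],
                                  factor_genes: list[str],
                                  profile: ConditionProfile,
                                  mode: str = "repressor") -> pd.DataFrame:
    """Descriptive table relating candidate factor expression to motif usage.

    For a repressor, its targets (the motif-hit genes) should be expressed
    where the factor itself is depleted; for an activator, where it is
    enriched.  One row per factor x condition, reporting the factor's
    relative level, the mean relative level of the motif-hit genes and
    whether the pair is consistent with ``mode``.  Missing factors are
    listed with absent=True.
    """
    rel = profile.means.sub(profile.means.mean(axis=1), axis=0)
    hit_genes = [g for g in motif_hit_genes if g in rel.index]
    hit_mean = rel.loc[hit_genes].mean(axis=0) if hit_genes else None
    rows = []
    for factor in factor_genes:
        absent = factor not in rel.index
        for cond in profile.conditions:
            row = {"factor": factor, "cell_type": cond[0], "organ": cond[1],
                   "absent": absent}
            if not absent and hit_mean is not None:
                f_rel = float(rel.loc[factor, cond])
                t_rel = float(hit_mean[cond])
                row["factor_relative"] = f_rel
                row["targets_relative"] = t_rel
                expected_opposite = (mode == "repressor")
                consistent = (f_rel * t_rel < 0) if expected_opposite else (f_rel * t_rel > 0)
                row["consistent"] = bool(consistent)
            rows.append(row)
    return pd.DataFrame(rows)
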