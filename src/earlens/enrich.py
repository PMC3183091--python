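"""Set over-representation, fold enrichment and rank-based de-repression.

Three statistics cover the downstream claims of the analysis:

* hypergeometric upper-tail over-representation of a query gene set in
  annotation sets (functional categories, disease-gene lists, clusters),
  with Benjamini-Hochberg q-values across the tested sets;
* fold enrichment arithmetic, (k/n) / background_rate, the "2.5-fold"
  style statement;
* a rank de-repression test for single-array mutant-vs-control contrasts:
  genes are sorted by log2 fold change, the positions of a marker set in
  the sorted list form a barcode, and a two-sided Wilcoxon rank-sum compares
  the marker fold changes with the rest.  With one array per genotype there
  is no per-gene inference — conclusions are set-level only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSet, GeneSetCollection
from .mirna import rank_sum
from .preprocess import log2_transform, quantile_normalize
from .signatures import ClusterResult, bh_fdr


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k) for drawing n from N with K annotated.

    Computed through the survival function in log space (numerically stable
    for extreme tails).
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if K > N or n > N or k > min(K, n):
        raise ValueError(f"inconsistent arguments k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fold_enrichment(observed_k: int, query_n: int, background_rate: float) -> float:
    """(k/n) / background_rate — observed rate over the expected rate."""
    if query_n <= 0:
        raise ValueError("query_n must be positive")
    if background_rate <= 0:
        raise ValueError("background_rate must be positive")
    return (observed_k / query_n) / background_rate


@dataclass
class EnrichmentResult:
    name: str
    N: int
    K: int
    n: int
    k: int
    p_hyper: float
    fold: float
    q: float | None = None

    @property
    def overlap_genes(self) -> None:
        return None  # populated only by set_overrepresentation tables


def set_overrepresentation(query: GeneSet, annotations: GeneSetCollection,
                           universe: set[str] | None = None) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each annotation set.

    Sets and query are trimmed to the universe first; q is BH across the
    tested sets.  Returns a DataFrame sorted by p.
    """
    uni = set(universe) if universe is not None else set(annotations.universe)
    q_genes = query.member_set & uni
    N, n = len(uni), len(q_genes)
    rows = []
    for gs in annotations:
        ann = gs.member_set & uni
        K = len(ann)
        k = len(ann & q_genes)
        p = hypergeom_tail(k, K, n, N) if (n and K) else 1.0
        expected_rate = K / N if N else 0.0
        fold = fold_enrichment(k, n, expected_rate) if (n and expected_rate) else 0.0
        rows.append({"set": gs.name, "N": N, "K": K, "n": n, "k": k,
                     "p_hyper": p, "fold": fold})
    table = pd.DataFrame(rows).set_index("set")
    table["q"] = bh_fdr(table["p_hyper"].to_numpy()) if len(table) else []
    return table.sort_values(["p_hyper", "k"], ascending=[True, False], kind="mergesort")


def cluster_bias(special_genes: GeneSet, clusters: ClusterResult,
                 focal_clusters: list[int]) -> EnrichmentResult:
    """Bias of a special gene list toward a union of expression clusters.

    Universe = all clustered genes; annotation = the focal-cluster union;
    reported p is the hypergeometric upper tail of the overlap.
    """
    universe = set(clusters.assignments.index)
    focal = {g for c in focal_clusters for g in clusters.members(c)}
    special = special_genes.member_set & universe
    k = len(special & focal)
    N, K, n = len(universe), len(focal), len(special)
    p = hypergeom_tail(k, K, n, N) if (n and K) else 1.0
    fold = fold_enrichment(k, n, K / N) if (n and K) else 0.0
    return EnrichmentResult(name="cluster_bias", N=N, K=K, n=n, k=k,
                            p_hyper=p, fold=fold)


# ---------------------------------------------------------------------------
# mutant-vs-control contrasts
# ---------------------------------------------------------------------------

def genotype_contrast(mutant: ExpressionMatrix, control: ExpressionMatrix,
                      joint_normalize: bool = True) -> pd.Series:
    """Per-gene log2 fold change, mutant minus control.

    Both matrices (single arrays allowed) are quantile-normalized together
    before the subtraction, so the contrast is not confounded by array-wide
    intensity differences.
    """
    if list(mutant.values.index) != list(control.values.index):
        raise ValueError("mutant and control must share the same gene index")
    if mutant.scale != control.scale:
        raise ValueError("mutant and control must be on the same scale")
    joint_values = pd.concat([mutant.values, control.values], axis=1)
    samples = list(mutant.samples) + list(control.samples)
    joint = ExpressionMatrix(values=joint_values, samples=samples,
                             probe_to_gene=mutant.probe_to_gene, scale=mutant.scale)
    if joint.scale == "linear":
        if joint_normalize:
            joint = quantile_normalize(joint)
        joint = log2_transform(joint)
    m_cols = mutant.sample_ids
    c_cols = control.sample_ids
    fc = joint.values[m_cols].mean(axis=1) - joint.values[c_cols].mean(axis=1)
    fc.name = "log2_fold_change"
    return fc


@dataclass
class RankEnrichmentResult:
    """Sorted fold-change list with the marker-set barcode and rank test."""

    sorted_genes: list[str]            # descending fold change
    fold_changes: pd.Series            # in sorted order
    barcode: list[int]                 # 1-based marker positions in sorted list
    statistic: float                   # rank-sum U statistic
    p: float | None
    direction: str | None              # '+': markers elevated, '-': depressed
    n_markers: int
    tested: bool


def rank_set_test(fold_changes: pd.Series, marker_set: GeneSet,
                  min_overlap: int = 10) -> RankEnrichmentResult:
    """Two-sided Wilcoxon rank-sum of marker fold changes against the rest.

    Invariant to any strictly monotone transform of the fold changes.  The
    barcode gives marker positions (1-based) along the descending-sorted
    list, the graphical "vertical bars" view of the enrichment.
    """
    fc = fold_changes.sort_values(ascending=False, kind="mergesort")
    in_set = fc.index.isin(marker_set.member_set)
    n = int(in_set.sum())
    barcode = [int(i) + 1 for i in np.flatnonzero(in_set)]
    if n < min_overlap:
        return RankEnrichmentResult(list(fc.index), fc, barcode, np.nan, None,
                                    None, n, tested=False)
    x = fc.to_numpy(dtype=float)[in_set]
    y = fc.to_numpy(dtype=float)[~in_set]
    u = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic").statistic)
    p = rank_sum(x, y)
    direction = "+" if np.median(x) > np.median(y) else "-"
    return RankEnrichmentResult(list(fc.index), fc, barcode, u, p, direction,
                                n, tested=True)


def zeb1_target_candidates(fold_changes: pd.Series, epithelial_markers: GeneSet,
                           motif_hit_genes: set[str],
                           fc_threshold: float = 1.0) -> pd.DataFrame:
    """De-repressed repressor-target candidates.

    Epithelial marker genes whose mutant-vs-control log2 fold change is at
    least ``fc_threshold`` and whose promoter carries the repressor's motif,
    sorted by fold change (descending).
    """
    rows = []
    for gene in epithelial_markers.member_set & set(fold_changes.index):
        fc = float(fold_changes[gene])
        if fc >= fc_threshold and gene in motif_hit_genes:
            rows.append({"gene": gene, "log2_fold_change": fc})
    table = pd.DataFrame(rows, columns=["gene", "log2_fold_change"])
    return table.sort_values(["log2_fold_change", "gene"],
                             ascending=[False, True], kind="mergesort").reset_index(drop=True)
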