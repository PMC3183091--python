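"""Differential expression, sample dendrogram, gene clustering, marker rule.

Differential genes are called by a classical balanced two-way fixed-effects
ANOVA per gene (factors: cell type and organ), flagging genes whose smallest
of the three p-values (cell type, organ, interaction) falls below 1e-5;
Benjamini-Hochberg q-values over that minimum p are reported alongside.
Cell-type markers follow the stringent linear-scale rule: a gene is a marker
of cell type t iff its minimum intensity over all samples of t is at least
``ratio`` (default 1.5, i.e. "50% higher") times its maximum over every
other cell type's samples — which makes marker sets provably disjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io import ConditionProfile, ExpressionMatrix


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Per-gene F statistics, p-values and the differential flag."""

    table: pd.DataFrame  # columns: F_cell, p_cell, F_organ, p_organ,
    #                       F_interaction, p_interaction, min_p, q,
    #                       is_differential, degenerate
    p_threshold: float
    fdr_threshold: float

    @property
    def differential_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_differential"]])


def two_way_anova(m: ExpressionMatrix, p_threshold: float = 1e-5,
                  fdr_threshold: float = 0.01) -> AnovaResult:
    """Balanced two-way fixed-effects ANOVA for every gene.

    Requires a complete cell_type x organ design with an equal number (>= 2)
    of replicates per cell.  Genes with zero residual variance are flagged
    degenerate: p = 1 where the factor sum of squares is also ~0 (flat gene),
    p = 0 where the factor explains all variation.
    """
    frame = m.sample_frame()
    cells = sorted(frame["cell_type"].unique())
    organs = sorted(frame["organ"].unique())
    a, b = len(cells), len(organs)
    counts = frame.groupby(["cell_type", "organ"]).size()
    if len(counts) != a * b or counts.nunique() != 1:
        raise ValueError("two_way_anova requires a balanced full factorial design")
    r = int(counts.iloc[0])
    if r < 2:
        raise ValueError("two_way_anova requires >= 2 replicates per cell")

    # reshape to genes x a x b x r in a fixed sample order
    order = []
    for ct in cells:
        for org in organs:
            sids = frame.index[(frame["cell_type"] == ct) & (frame["organ"] == org)]
            order.extend(sorted(sids))
    y = m.values[order].to_numpy(dtype=float).reshape(m.n_probes, a, b, r)

    grand = y.mean(axis=(1, 2, 3))
    mean_ab = y.mean(axis=3)
    mean_a = y.mean(axis=(2, 3))
    mean_b = y.mean(axis=(1, 3))
    g = grand[:, None]
    ss_cell = b * r * ((mean_a - g) ** 2).sum(axis=1)
    ss_organ = a * r * ((mean_b - g) ** 2).sum(axis=1)
    ss_inter = r * ((mean_ab - mean_a[:, :, None] - mean_b[:, None, :]
                     + grand[:, None, None]) ** 2).sum(axis=(1, 2))
    ss_err = ((y - mean_ab[:, :, :, None]) ** 2).sum(axis=(1, 2, 3))

    df_cell, df_organ = a - 1, b - 1
    df_inter, df_err = (a - 1) * (b - 1), a * b * (r - 1)
    ms_err = ss_err / df_err
    degenerate = ms_err <= 0

    def f_and_p(ss, df):
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss / df) / ms_err
        p = stats.f.sf(F, df, df_err)
        # zero residual variance: factor SS ~ 0 means a flat gene (p = 1),
        # otherwise the factor explains everything (p = 0)
        flat = degenerate & (ss <= 1e-12)
        p = np.where(degenerate, np.where(flat, 1.0, 0.0), p)
        F = np.where(degenerate, np.where(flat, 0.0, np.inf), F)
        return F, p

    F_cell, p_cell = f_and_p(ss_cell, df_cell)
    F_organ, p_organ = f_and_p(ss_organ, df_organ)
    F_inter, p_inter = f_and_p(ss_inter, df_inter)
    min_p = np.minimum(np.minimum(p_cell, p_organ), p_inter)
    q = bh_fdr(min_p)
    table = pd.DataFrame({
        "F_cell": F_cell, "p_cell": p_cell,
        "F_organ": F_organ, "p_organ": p_organ,
        "F_interaction": F_inter, "p_interaction": p_inter,
        "min_p": min_p, "q": q,
        "is_differential": min_p < p_threshold,
        "degenerate": degenerate,
    }, index=m.values.index)
    return AnovaResult(table=table, p_threshold=p_threshold, fdr_threshold=fdr_threshold)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# sample dendrogram
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    linkage: np.ndarray        # scipy linkage matrix
    sample_ids: list[str]

    def cut(self, k: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.sample_ids, (int(x) for x in labels)))

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def hierarchical_samples(m: ExpressionMatrix, distance: str = "correlation",
                         linkage: str = "average") -> Dendrogram:
    """Average-linkage agglomeration of samples under 1 - Pearson distance."""
    if len(m.samples) < 3:
        raise ValueError("need >= 3 samples for a dendrogram")
    x = m.values.to_numpy(dtype=float).T  # samples x genes
    if distance == "correlation" and (x.std(axis=1) == 0).any():
        raise ValueError(
            "constant sample vector has undefined correlation distance; "
            "use distance='euclidean'"
        )
    d = pdist(x, metric=distance)
    z = hierarchy.linkage(d, method=linkage)
    return Dendrogram(linkage=z, sample_ids=m.sample_ids)


# ---------------------------------------------------------------------------
# gene clustering
# ---------------------------------------------------------------------------

def standardize_rows(profile: ConditionProfile) -> ConditionProfile:
    """Standardize each gene's condition pattern to mean 0, population SD 1.

    Constant rows carry no pattern and are dropped with a warning.
    """
    x = profile.means.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population SD (ddof=0)
    constant = (sd[:, 0] == 0)
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant rows before clustering")
    z = (x[~constant] - mu[~constant]) / sd[~constant]
    means = pd.DataFrame(z, index=profile.means.index[~constant],
                         columns=profile.means.columns)
    return ConditionProfile(means=means)


@dataclass
class ClusterResult:
    assignments: pd.Series         # gene -> cluster id (1-based)
    patterns: pd.DataFrame         # cluster x condition mean of standardized rows
    pattern_sd: pd.DataFrame       # cluster x condition SD
    k: int
    seed: int
    restarts: int
    inertia: float

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()

    def members(self, cluster_id: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster_id])


def kmeans_genes(std_profile: ConditionProfile, k: int = 8, seed: int = 0,
                 restarts: int = 20) -> ClusterResult:
    """k-means over standardized condition patterns, best of ``restarts``
    k-means++ initializations; reports each cluster's mean pattern +/- SD."""
    x = std_profile.means.to_numpy(dtype=float)
    n_distinct = np.unique(x, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct patterns")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(x) + 1
    assignments = pd.Series(labels, index=std_profile.means.index, name="cluster")
    rows_mean, rows_sd = [], []
    for c in range(1, k + 1):
        sub = x[labels == c]
        rows_mean.append(sub.mean(axis=0))
        rows_sd.append(sub.std(axis=0))
    patterns = pd.DataFrame(rows_mean, index=range(1, k + 1),
                            columns=std_profile.means.columns)
    pattern_sd = pd.DataFrame(rows_sd, index=range(1, k + 1),
                              columns=std_profile.means.columns)
    return ClusterResult(assignments=assignments, patterns=patterns,
                         pattern_sd=pattern_sd, k=k, seed=seed,
                         restarts=restarts, inertia=float(km.inertia_))


# ---------------------------------------------------------------------------
# marker rule
# ---------------------------------------------------------------------------

@dataclass
class MarkerAssignment:
    """gene -> (cell type or None, margin = min_in_type / max_out_of_type)."""

    table: pd.DataFrame  # columns: cell_type (str or NaN), margin
    ratio: float

    def markers_of(self, cell_type: str) -> list[str]:
        mask = self.table["cell_type"] == cell_type
        return list(self.table.index[mask])

    def as_dict(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for ct in self.table["cell_type"].dropna().unique():
            out[ct] = set(self.markers_of(ct))
        return out


def define_markers(m: ExpressionMatrix, ratio: float = 1.5) -> MarkerAssignment:
    """Assign marker genes on the linear scale.

    A gene is a marker of cell type t iff min over t's samples (both organs)
    >= ratio * max over every other cell type's samples; the boundary is
    inclusive.  For ratio > 1 at most one cell type can qualify, so marker
    sets are disjoint by construction.  Invariant to global rescaling.
    """
    if m.scale != "linear":
        raise ValueError("marker rule is a linear-scale (fold) statement")
    frame = m.sample_frame()
    wt = frame[[m.descriptor(s).is_wildtype() and m.descriptor(s).compartment is None
                for s in frame.index]]
    cell_types = sorted(wt["cell_type"].unique())
    x = m.values[list(wt.index)].to_numpy(dtype=float)
    cols = {ct: [i for i, s in enumerate(wt.index) if wt.loc[s, "cell_type"] == ct]
            for ct in cell_types}
    mins = {ct: x[:, idx].min(axis=1) for ct, idx in cols.items()}
    maxs = {ct: x[:, idx].max(axis=1) for ct, idx in cols.items()}

    assigned = np.full(m.n_probes, None, dtype=object)
    margin = np.full(m.n_probes, np.nan)
    for ct in cell_types:
        others = [o for o in cell_types if o != ct]
        out_max = np.max(np.column_stack([maxs[o] for o in others]), axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio_vec = mins[ct] / out_max
        hit = mins[ct] >= ratio * out_max
        assigned[hit] = ct
        margin[hit] = ratio_vec[hit]
    table = pd.DataFrame({"cell_type": assigned, "margin": margin},
                         index=m.values.index)
    return MarkerAssignment(table=table, ratio=ratio)
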