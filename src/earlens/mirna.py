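"""miRNA family activity inferred from target-set expression signatures.

An active miRNA down-regulates dozens of its predicted target mRNAs, so a
target set that sits significantly below the rest of the transcriptome in a
cell population marks that miRNA as active there.  For each family and each
(cell type, organ) condition, the relative expression levels (each gene's
log2 condition mean minus its mean across all conditions) of the predicted
targets are compared with all remaining genes by a two-sided Wilcoxon
rank-sum test; the activity grid reports direction (-: targets depleted,
+: elevated) and flags significance at p <= 1e-5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ConditionProfile, GeneSet, GeneSetCollection


@dataclass
class RelativeProfile:
    """Row-centered log2 condition means; every row sums to ~0."""

    values: pd.DataFrame  # genes x (cell_type, organ) MultiIndex columns

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[tuple[str, str]]:
        return list(self.values.columns)


def relative_levels(profile: ConditionProfile) -> RelativeProfile:
    """Normalize each gene to its average level across the conditions."""
    x = profile.means
    return RelativeProfile(values=x.sub(x.mean(axis=1), axis=0))


def rank_sum(x: np.ndarray, y: np.ndarray, exact_max: int = 25) -> float:
    """Two-sided Wilcoxon rank-sum p: exact when both groups are small
    (<= ``exact_max``), tie-corrected normal approximation otherwise."""
    method = "exact" if (len(x) <= exact_max and len(y) <= exact_max) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def target_set_test(rel: RelativeProfile, targets: GeneSet,
                    condition: tuple[str, str],
                    min_set_size: int = 20) -> tuple[str | None, float | None, int]:
    """Compare a target set against all remaining genes in one condition.

    Returns (direction, p, n_targets_tested); direction is the sign of the
    median difference (targets minus background).  Sets smaller than
    ``min_set_size`` after intersection with the profile are left untested
    (direction and p are None).
    """
    universe = rel.values.index
    in_set = universe.isin(targets.member_set)
    n = int(in_set.sum())
    if n < min_set_size:
        return None, None, n
    col = rel.values[condition].to_numpy(dtype=float)
    tvals, bvals = col[in_set], col[~in_set]
    p = rank_sum(tvals, bvals)
    direction = "-" if np.median(tvals) < np.median(bvals) else "+"
    return direction, p, n


@dataclass
class MiRNAActivityTable:
    """Family x condition grid of (direction, p, significant) - the activity
    matrix of the analysis."""

    directions: pd.DataFrame   # str ("+"/"-") or NaN for untested
    p_values: pd.DataFrame
    n_targets: pd.Series       # per family
    alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.p_values.le(self.alpha) & self.p_values.notna()

    def summary(self) -> pd.DataFrame:
        """Long-form table: family, cell_type, organ, direction, p, significant."""
        rows = []
        for fam in self.p_values.index:
            for cond in self.p_values.columns:
                p = self.p_values.loc[fam, cond]
                rows.append({
                    "family": fam,
                    "cell_type": cond[0],
                    "organ": cond[1],
                    "direction": self.directions.loc[fam, cond],
                    "p": p,
                    "significant": bool(p <= self.alpha) if pd.notna(p) else False,
                    "n_targets": int(self.n_targets[fam]),
                })
        return pd.DataFrame(rows)


def activity_table(rel: RelativeProfile, target_collection: GeneSetCollection,
                   alpha: float = 1e-5, min_set_size: int = 20) -> MiRNAActivityTable:
    """Full family x condition activity grid.

    Significance is p <= ``alpha`` (default 1e-5, the grid's NS cut); raw p
    is retained for every tested cell.
    """
    conds = rel.conditions
    fams = target_collection.names
    directions = pd.DataFrame(index=fams, columns=pd.MultiIndex.from_tuples(conds),
                              dtype=object)
    p_values = pd.DataFrame(np.nan, index=fams,
                            columns=pd.MultiIndex.from_tuples(conds))
    n_targets = pd.Series(0, index=fams, dtype=int)
    for fam in fams:
        gs = target_collection[fam]
        for cond in conds:
            direction, p, n = target_set_test(rel, gs, cond, min_set_size=min_set_size)
            n_targets[fam] = n
            if p is not None:
                directions.loc[fam, cond] = direction
                p_values.loc[fam, cond] = p
    return MiRNAActivityTable(directions=directions, p_values=p_values,
                              n_targets=n_targets, alpha=alpha)
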