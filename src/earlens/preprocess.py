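"""Probe filtering, quantile normalization, log transform and collapsing.

The fixed stage order is: detection filter (linear scale) -> quantile
normalization (linear) -> log2 transform -> probe-to-gene collapse ->
condition means.  Quantile normalization runs on linear intensities before
the log transform, matching common BeadChip practice.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import ConditionProfile, ExpressionMatrix


def filter_detected(m: ExpressionMatrix, p_thresh: float = 0.01,
                    min_samples: int = 2) -> ExpressionMatrix:
    """Keep probes detected (detection p strictly below ``p_thresh``) in at
    least ``min_samples`` samples.  Probe order is preserved; idempotent."""
    if m.detection_p is None:
        raise ValueError(
            "detection p-values absent; pass the detection matrix or skip "
            "filter_detected explicitly"
        )
    n_det = (m.detection_p.to_numpy() < p_thresh).sum(axis=1)
    keep = [p for p, n in zip(m.probe_ids, n_det) if n >= min_samples]
    return m.subset_probes(keep)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column onto the common distribution of rank means.

    Each column's sorted values are replaced by the cross-column mean of
    sorted values at that rank; ties within a column receive the mean of
    their tied reference quantiles, so the map is rank-preserving.
    """
    x = m.values.to_numpy(dtype=float)
    n, s = x.shape
    if s < 2:
        warnings.warn("quantile normalization with a single sample is the identity")
        return m
    order = np.argsort(x, axis=0, kind="mergesort")
    ref = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(s):
        col_order = order[:, j]
        out[col_order, j] = ref
        sorted_vals = x[col_order, j]
        # average the reference over runs of tied values
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        run_means = np.add.reduceat(ref, starts) / (ends - starts)
        for st, en, mu in zip(starts, ends, run_means):
            if en - st > 1:
                out[col_order[st:en], j] = mu
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=values, samples=list(m.samples),
                            probe_to_gene=m.probe_to_gene,
                            detection_p=m.detection_p, scale=m.scale)


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(x + offset); flips the scale flag from linear to log2."""
    if m.scale != "linear":
        raise ValueError("matrix already on log2 scale")
    x = m.values.to_numpy(dtype=float)
    if (x + offset <= 0).any():
        raise ValueError("values <= -offset cannot be log-transformed")
    values = pd.DataFrame(np.log2(x + offset), index=m.values.index,
                          columns=m.values.columns)
    return ExpressionMatrix(values=values, samples=list(m.samples),
                            probe_to_gene=m.probe_to_gene,
                            detection_p=m.detection_p, scale="log2")


def collapse_probes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse to gene level, keeping each gene's highest-mean probe.

    Unmapped probes are dropped.  The max-mean policy (rather than
    averaging) preserves the dynamic range of the best-responding probe.
    """
    mapped = [p for p in m.probe_ids if p in m.probe_to_gene]
    if not mapped:
        raise ValueError("no probes are mapped to genes; collapse would be empty")
    sub = m.values.loc[mapped]
    gene_of = pd.Series([m.probe_to_gene[p] for p in mapped], index=mapped)
    probe_means = sub.mean(axis=1)
    # highest-mean probe per gene; ties broken by probe id for determinism
    rank = pd.DataFrame({"gene": gene_of, "mean": probe_means})
    rank = rank.sort_values(["gene", "mean"], ascending=[True, False], kind="mergesort")
    chosen = rank.drop_duplicates("gene", keep="first")
    values = sub.loc[chosen.index]
    values.index = chosen["gene"].to_numpy()
    dp = None
    if m.detection_p is not None:
        dp = m.detection_p.loc[chosen.index]
        dp.index = values.index
    return ExpressionMatrix(values=values, samples=list(m.samples),
                            probe_to_gene={g: g for g in values.index},
                            detection_p=dp, scale=m.scale)


def condition_means(m: ExpressionMatrix) -> ConditionProfile:
    """Average replicates within each (cell_type, organ) condition."""
    if m.scale != "log2":
        raise ValueError("condition means are defined on the log2 scale")
    frame = m.sample_frame()
    groups: dict[tuple[str, str], list[str]] = {}
    for sid, row in frame.iterrows():
        groups.setdefault((row["cell_type"], row["organ"]), []).append(sid)
    cols = {cond: m.values[sids].mean(axis=1) for cond, sids in groups.items()}
    means = pd.DataFrame(cols)
    means.columns = pd.MultiIndex.from_tuples(cols.keys(), names=["cell_type", "organ"])
    return ConditionProfile(means=means)


def preprocess(m: ExpressionMatrix, p_thresh: float = 0.01, min_samples: int = 2,
               do_filter: bool = True) -> ExpressionMatrix:
    """Run filter -> quantile -> log2 -> collapse and return the gene-level
    log2 matrix."""
    if do_filter:
        m = filter_detected(m, p_thresh=p_thresh, min_samples=min_samples)
    m = quantile_normalize(m)
    m = log2_transform(m)
    return collapse_probes(m)
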