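"""Candidate-gene prioritization within disease-locus intervals.

Given a linkage interval for an uncloned deafness locus, the genes inside
it are ranked by expression evidence: selective expression in the expected
cell type ranks first, then membership in an expression-interaction module
shared with known disease genes, then plain expression in the dataset.
"Selectively expressed" is either the strict marker rule or (configurable)
a relative-level dominance of >= 1 log2 over every other cell type — the
looser reading needed when the strict rule finds nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ConditionProfile, GeneLocation, GeneSet, LocusInterval
from .netmod import ModuleResult
from .signatures import MarkerAssignment


def genes_in_locus(locus: LocusInterval, genes: list[GeneLocation]) -> list[GeneLocation]:
    """Genes whose interval overlaps the locus (any overlap, half-open)."""
    return [g for g in genes
            if g.chrom == locus.chrom and g.start < locus.end and locus.start < g.end]


@dataclass
class CandidateReport:
    locus: str
    genes_in_locus: list[str]
    expressed: list[str]
    selective: dict[str, str]          # gene -> cell type it is selective for
    module_members: dict[str, int]     # gene -> module index
    ranking: pd.DataFrame = field(default=None)

    def top(self, n: int = 5) -> list[str]:
        return list(self.ranking.index[:n])


def _selective_by_relative_level(profile: ConditionProfile, gene: str,
                                 margin: float = 1.0) -> str | None:
    """Cell type whose conditions all exceed every other cell type's
    conditions by >= margin log2 in relative level, if any."""
    if gene not in profile.means.index:
        return None
    row = profile.means.loc[gene]
    by_ct = row.groupby(level="cell_type")
    ct_min = by_ct.min()
    ct_max = by_ct.max()
    for ct in ct_min.index:
        others = ct_max.drop(ct)
        if ct_min[ct] >= others.max() + margin:
            return ct
    return None


def prioritize(locus: LocusInterval, gene_locations: list[GeneLocation],
               expressed_genes: set[str], markers: MarkerAssignment | None,
               modules: list[ModuleResult] | None = None,
               known_disease_genes: set[str] | None = None,
               expected_cell_type: str | None = None,
               profile: ConditionProfile | None = None,
               selectivity: str = "marker") -> CandidateReport:
    """Rank candidate genes within a locus by expression evidence.

    Evidence tiers (best first):

    1. selectively expressed in ``expected_cell_type`` (marker rule, or
       relative-level dominance when ``selectivity='relative'``);
    2. member of an expression-interaction module that also contains a known
       disease gene (physically connected to the disease machinery);
    3. expressed in the dataset at all.

    Ties break by marker margin (descending) then gene id, so the order is
    a deterministic total order.  A locus without genes yields an empty
    report.
    """
    modules = modules or []
    known = known_disease_genes or set()
    located = genes_in_locus(locus, gene_locations)
    gene_ids = sorted(g.gene_id for g in located)
    expressed = [g for g in gene_ids if g in expressed_genes]

    selective: dict[str, str] = {}
    margins: dict[str, float] = {}
    for g in expressed:
        ct = None
        if markers is not None and g in markers.table.index:
            val = markers.table.loc[g, "cell_type"]
            if pd.notna(val):
                ct = str(val)
                margins[g] = float(markers.table.loc[g, "margin"])
        if ct is None and selectivity == "relative" and profile is not None:
            ct = _selective_by_relative_level(profile, g)
        if ct is not None:
            selective[g] = ct

    module_members: dict[str, int] = {}
    for mi, mod in enumerate(modules):
        if not (set(mod.genes) & known):
            continue  # module carries disease evidence only if it holds a known gene
        for g in expressed:
            if g in set(mod.genes):
                module_members.setdefault(g, mi)

    rows = []
    for g in expressed:
        tier1 = (expected_cell_type is not None and selective.get(g) == expected_cell_type)
        tier2 = g in module_members
        tier = 1 if tier1 else (2 if tier2 else 3)
        rows.append({
            "gene": g,
            "tier": tier,
            "selective_cell_type": selective.get(g, ""),
            "marker_margin": margins.get(g, np.nan),
            "module": module_members.get(g, -1),
            "expressed": True,
        })
    ranking = pd.DataFrame(rows, columns=["gene", "tier", "selective_cell_type",
                                          "marker_margin", "module", "expressed"])
    if len(ranking):
        ranking["_margin_key"] = ranking["marker_margin"].fillna(-np.inf)
        ranking = ranking.sort_values(["tier", "_margin_key", "gene"],
                                      ascending=[True, False, True],
                                      kind="mergesort").drop(columns="_margin_key")
        ranking = ranking.set_index("gene")
    else:
        ranking = ranking.set_index("gene") if "gene" in ranking else ranking
    return CandidateReport(
        locus=locus.name,
        genes_in_locus=gene_ids,
        expressed=expressed,
        selective=selective,
        module_members=module_members,
        ranking=ranking,
    )


def verify_report(report: CandidateReport, gene_locations: list[GeneLocation],
                  locus: LocusInterval, expressed_genes: set[str]) -> bool:
    """Independently recompute the report's containment claims."""
    located = {g.gene_id for g in gene_locations
               if g.chrom == locus.chrom and g.start < locus.end and locus.start < g.end}
    if set(report.genes_in_locus) != located:
        return False
    if set(report.expressed) != located & expressed_genes:
        return False
    return set(report.selective) <= set(report.expressed)
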