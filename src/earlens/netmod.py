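"""Expression-interaction modules: connected, co-expressed subnetworks.

Searches a protein-protein interaction graph for connected groups of genes
with coherent expression patterns across the (cell type, organ) conditions.
The optimizer is a deterministic greedy seed-and-extend: seed on the
highest-similarity edges, repeatedly add the neighboring gene that most
improves the score

    score = mean pairwise Pearson similarity among front genes - lambda * |back|

where "front" genes match the module's expression pattern and "back" genes
are connectors kept only to preserve connectivity (the box nodes of the
module view).  A gene whose mean similarity to the current front falls
below seed_threshold/2 may enter only as a back gene, and only if it
either bridges components or opens a higher-scoring front addition within
two steps.

The greedy gain is evaluated on the threshold-shifted objective

    sum over front pairs of (sim_ij - seed_threshold) - lambda * |back|

so adding a gene is profitable exactly when its mean similarity to the
current front exceeds the seed threshold; a raw mean-pairwise score would
stall immediately, since any addition below the current mean lowers it.
The reported module score stays on the mean-pairwise scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from .io import ConditionProfile, GeneSet, GeneSetCollection
from .enrich import set_overrepresentation


def similarity_matrix(profile: ConditionProfile,
                      genes: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlation of standardized condition patterns, gene x gene."""
    x = profile.means
    if genes is not None:
        x = x.loc[[g for g in genes if g in x.index]]
    arr = x.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    keep = sd > 0
    arr = arr[keep]
    idx = x.index[keep]
    z = (arr - arr.mean(axis=1, keepdims=True)) / arr.std(axis=1, keepdims=True)
    sim = (z @ z.T) / z.shape[1]
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=idx, columns=idx)


@dataclass
class ModuleResult:
    front: list[str]
    back: list[str]
    score: float
    spanning_tree: list[tuple[str, str]]   # connectivity certificate
    trace: list[float] = field(default_factory=list)  # score after each step

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.front) | set(self.back))

    def __len__(self) -> int:
        return len(self.front) + len(self.back)


def _mean_pairwise(sim: np.ndarray, idx: list[int]) -> float:
    if len(idx) < 2:
        return 0.0
    sub = sim[np.ix_(idx, idx)]
    n = len(idx)
    return float((sub.sum() - n) / (n * (n - 1)))


def find_modules(network: nx.Graph, sim: pd.DataFrame,
                 seed_threshold: float = 0.8, min_size: int = 8,
                 max_size: int = 60, lam: float = 0.05) -> list[ModuleResult]:
    """Greedy seed-and-extend module search (deterministic).

    Seeds are network edges whose endpoints have similarity >=
    ``seed_threshold``, visited in decreasing similarity (ties by gene ids).
    Genes assigned to a module are removed before the next seed.  Modules
    smaller than ``min_size`` are discarded.
    """
    if network.number_of_nodes() == 0:
        return []
    genes = [g for g in sim.index if g in network]
    pos = {g: i for i, g in enumerate(genes)}
    s = sim.loc[genes, genes].to_numpy(dtype=float)

    seeds = []
    for u, v in network.edges():
        if u in pos and v in pos and s[pos[u], pos[v]] >= seed_threshold:
            a, b = sorted((u, v))
            seeds.append((-s[pos[u], pos[v]], a, b))
    seeds.sort()

    assigned: set[str] = set()
    modules: list[ModuleResult] = []
    for _, u, v in seeds:
        if u in assigned or v in assigned:
            continue
        front = [u, v]
        back: list[str] = []
        trace = []

        def score(front_list, back_list):
            idx = [pos[g] for g in front_list]
            n_pairs = len(idx) * (len(idx) - 1) / 2
            return (n_pairs * (_mean_pairwise(s, idx) - seed_threshold)
                    - lam * len(back_list))

        current = score(front, back)
        trace.append(current)
        while len(front) + len(back) < max_size:
            members = set(front) | set(back)
            neighbors = sorted({
                nb for g in members for nb in network.neighbors(g)
                if nb in pos and nb not in members and nb not in assigned
            })
            if not neighbors:
                break
            front_idx = [pos[g] for g in front]
            best = None  # (gain, kind, gene, extra_front)
            for cand in neighbors:
                mean_sim = float(s[pos[cand], front_idx].mean())
                if mean_sim >= seed_threshold / 2:
                    gain = score(front + [cand], back) - current
                    if gain > 0 and (best is None or gain > best[0]):
                        best = (gain, "front", cand, None)
                else:
                    # back candidate: admissible if it bridges, or if some
                    # neighbor of it becomes a profitable front addition
                    # within two steps
                    bridges = _connects_components(network, cand, front, back)
                    two_step = None
                    for nb in sorted(network.neighbors(cand)):
                        if nb in pos and nb not in members and nb not in assigned:
                            nb_sim = float(s[pos[nb], front_idx].mean())
                            if nb_sim >= seed_threshold / 2:
                                gain2 = score(front + [nb], back + [cand]) - current
                                if gain2 > 0 and (two_step is None or gain2 > two_step[0]):
                                    two_step = (gain2, nb)
                    if two_step is not None:
                        gain, nb = two_step
                        if best is None or gain > best[0]:
                            best = (gain, "back+front", cand, nb)
                    elif bridges:
                        gain = score(front, back + [cand]) - current
                        if gain > 0 and (best is None or gain > best[0]):
                            best = (gain, "back", cand, None)
            if best is None:
                break
            _, kind, cand, extra = best
            if kind == "front":
                front.append(cand)
            elif kind == "back":
                back.append(cand)
            else:
                back.append(cand)
                front.append(extra)
            current = score(front, back)
            trace.append(current)

        if len(front) + len(back) >= min_size:
            sub = network.subgraph(front + back)
            if nx.is_connected(sub):
                tree = list(nx.bfs_tree(sub, sorted(sub.nodes)[0]).edges())
                mean_score = (_mean_pairwise(s, [pos[g] for g in front])
                              - lam * len(back))
                modules.append(ModuleResult(front=sorted(front), back=sorted(back),
                                            score=mean_score, spanning_tree=tree,
                                            trace=trace))
                assigned.update(front)
                assigned.update(back)
    return modules


def _connects_components(network: nx.Graph, cand: str, front: list[str],
                         back: list[str]) -> bool:
    """Would ``cand`` join >= 2 components of the current induced subgraph?"""
    sub = network.subgraph(front + back)
    comps = list(nx.connected_components(sub))
    if len(comps) < 2:
        return False
    touched = sum(1 for comp in comps if any(network.has_edge(cand, g) for g in comp))
    return touched >= 2


def annotate_module(module: ModuleResult, annotations: GeneSetCollection,
                    disease_genes: GeneSet,
                    loci_hits: dict[str, list[str]] | None = None) -> dict:
    """Decorate a module: per-gene disease/locus flags plus front-gene
    over-representation in the annotation sets."""
    loci_hits = loci_hits or {}
    in_locus = {g for genes in loci_hits.values() for g in genes}
    gene_flags = {
        g: {
            "front": g in set(module.front),
            "known_disease_gene": g in disease_genes.member_set,
            "in_uncloned_locus": g in in_locus,
        }
        for g in module.genes
    }
    front_set = GeneSet("module_front", "front genes", tuple(sorted(module.front)))
    enrichment = set_overrepresentation(front_set, annotations)
    return {"genes": gene_flags, "enrichment": enrichment, "score": module.score}
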