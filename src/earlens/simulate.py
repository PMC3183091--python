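"""Synthetic microarray datasets with planted, recoverable signals.

The generator emulates a balanced factorial BeadChip-style study of sorted
inner-ear cell populations: four cell types (sensory, neuronal, endothelial,
mesenchymal) from two organs (cochlea, vestibule) in triplicate, 24 arrays.
On the log2 scale each gene has a Normal(8, 1.5) baseline, i.i.d. Gaussian
within-condition noise (sigma = 0.25), and the following planted effects,
all recorded in :class:`~earlens.io.SyntheticTruth`:

* cell-type markers: +2 log2 in one cell type (both organs);
* an organ effect restricted to sensory markers (half elevated in the
  cochlea, half in the vestibule) so the sample dendrogram splits sensory
  samples by organ below the main cell-type partition;
* one active miRNA family whose target set is shifted -0.6 log2 in the two
  sensory conditions and +0.4 in the two mesenchymal conditions (the
  epithelial/mesenchymal two-sided pattern); the other families are null;
* an 8-mer promoter motif planted at rate 0.4 in sensory-marker promoters
  and 0.04 elsewhere, on a uniformly random strand and offset;
* a 25-gene co-expression module wired densely into a background
  interaction network;
* one cell-type-selective causal gene per disease locus.

Reported intensities are linear (2**log2); detection p-values follow a
logistic dropout model p = 1/(1 + exp(a*(log2 x - b))) with a=3, b=6.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
import networkx as nx

from .io import (
    CELL_TYPES,
    ORGANS,
    ExpressionMatrix,
    GeneLocation,
    GeneSet,
    GeneSetCollection,
    LocusInterval,
    PromoterSet,
    SampleDescriptor,
    SyntheticTruth,
    reverse_complement,
)


class ConfigError(ValueError):
    """Raised when a simulation configuration is infeasible."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_genes: int = 12000
    n_replicates: int = 3
    cell_types: tuple[str, ...] = CELL_TYPES
    organs: tuple[str, ...] = ORGANS
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25
    marker_effect: float = 2.0          # log2 boost in the marker's cell type
    markers_per_type: int = 300
    organ_effect: float = 1.0           # log2, sensory markers only
    n_mirna_families: int = 4
    targets_per_family: int = 250
    mirna_down_shift: float = -0.6      # planted family, sensory conditions
    mirna_up_shift: float = 0.4         # planted family, mesenchymal conditions
    motif_consensus: str = "CACCTGTC"
    motif_target_rate: float = 0.4
    motif_background_rate: float = 0.04
    promoter_upstream: int = 1000
    promoter_downstream: int = 200
    network_genes: int = 400
    network_edge_prob: float = 0.01
    module_size: int = 25
    module_edge_prob: float = 0.6
    module_pattern_sd: float = 1.2      # scale of the shared module profile
    n_loci: int = 4
    genes_per_locus: int = 12
    detection_a: float = 3.0
    detection_b: float = 6.0
    seed: int = 0
    # Twirler-style mutant arrays
    twirler_fraction: float = 0.6       # pi: epithelial markers de-repressed
    twirler_shift: float = 1.5          # d_full, log2, Tw_hom CD326neg
    twirler_het_vestibule_shift: float = 0.75
    twirler_mesenchymal_shift: float = -1.0
    compartment_effect: float = 2.0     # epithelial markers up in CD326pos

    def __post_init__(self):
        for rate in (self.motif_target_rate, self.motif_background_rate,
                     self.network_edge_prob, self.module_edge_prob,
                     self.twirler_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"rate {rate} outside [0, 1]")
        n_reserved = (len(self.cell_types) * self.markers_per_type
                      + self.n_mirna_families * self.targets_per_family
                      + self.module_size + self.n_loci * self.genes_per_locus)
        if n_reserved > self.n_genes:
            raise ConfigError(
                f"planted signals need {n_reserved} genes but n_genes={self.n_genes}"
            )
        if set(self.motif_consensus) - set("ACGT"):
            raise ConfigError("motif consensus must be over ACGT")
        if not 4 <= len(self.motif_consensus) <= 12:
            raise ConfigError("motif consensus length must be in 4..12")

    @property
    def conditions(self) -> list[tuple[str, str]]:
        return [(ct, org) for ct in self.cell_types for org in self.organs]

    def null(self) -> "SimulationConfig":
        """Copy with every planted effect switched off (global null)."""
        return replace(
            self,
            marker_effect=0.0,
            organ_effect=0.0,
            mirna_down_shift=0.0,
            mirna_up_shift=0.0,
            motif_target_rate=self.motif_background_rate,
            module_pattern_sd=0.0,
            twirler_fraction=0.0,
        )


@dataclass
class SyntheticDataset:
    """Bundle returned by :func:`generate_dataset`."""

    matrix: ExpressionMatrix
    promoters: PromoterSet
    mirna_targets: GeneSetCollection
    network: nx.Graph
    loci: list[LocusInterval]
    gene_locations: list[GeneLocation]
    truth: SyntheticTruth
    config: SimulationConfig = field(repr=False, default=None)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _random_sequences(rng: np.random.Generator, n: int, length: int) -> list[str]:
    codes = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [bytes(lut[row]).decode() for row in codes]


def generate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate the full factorial wild-type dataset plus side inputs.

    Deterministic for a fixed ``config`` (including its seed).
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    conditions = cfg.conditions
    n_cond = len(conditions)
    truth = SyntheticTruth()

    # -- allocate disjoint blocks of genes for each planted signal ----------
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        block = genes[cursor:cursor + n]
        cursor += n
        return block

    markers = {ct: take(cfg.markers_per_type) for ct in cfg.cell_types}
    family_names = [f"miR-fam{i + 1}" for i in range(cfg.n_mirna_families)]
    targets = {name: take(cfg.targets_per_family) for name in family_names}
    module_genes = take(cfg.module_size)
    locus_blocks = [take(cfg.genes_per_locus) for _ in range(cfg.n_loci)]

    # -- effects on the log2 scale, genes x conditions ----------------------
    effects = np.zeros((cfg.n_genes, n_cond))
    cond_idx = {c: j for j, c in enumerate(conditions)}
    gene_idx = {g: i for i, g in enumerate(genes)}

    for ct, block in markers.items():
        rows = [gene_idx[g] for g in block]
        for org in cfg.organs:
            effects[rows, cond_idx[(ct, org)]] += cfg.marker_effect
        truth.planted_markers[ct] = set(block)

    # organ split confined to sensory markers: half up in each organ
    if "sensory" in markers and len(cfg.organs) == 2:
        sens = markers["sensory"]
        half = len(sens) // 2
        for sub, org in ((sens[:half], cfg.organs[0]), (sens[half:], cfg.organs[1])):
            rows = [gene_idx[g] for g in sub]
            effects[rows, cond_idx[("sensory", org)]] += cfg.organ_effect

    # one active miRNA family (the first): targets repressed in sensory,
    # elevated in mesenchymal; remaining families are null decoys
    planted_family = family_names[0]
    fam_effects: list[tuple[tuple[str, str], float]] = []
    rows = [gene_idx[g] for g in targets[planted_family]]
    for ct, shift in (("sensory", cfg.mirna_down_shift), ("mesenchymal", cfg.mirna_up_shift)):
        if ct in cfg.cell_types and shift != 0.0:
            for org in cfg.organs:
                effects[rows, cond_idx[(ct, org)]] += shift
                fam_effects.append(((ct, org), shift))
    truth.planted_mirna_effects = {name: (fam_effects if name == planted_family else [])
                                   for name in family_names}
    truth.planted_mirna_targets = {name: set(block) for name, block in targets.items()}

    # coherent module profile shared (with per-gene amplitude) by module genes
    pattern = rng.normal(0.0, cfg.module_pattern_sd, size=n_cond)
    amp = rng.uniform(0.8, 1.2, size=cfg.module_size)
    effects[[gene_idx[g] for g in module_genes], :] += np.outer(amp, pattern)
    truth.planted_module = set(module_genes)

    # one causal, cell-type-selective gene per locus (cycled over cell types)
    loci: list[LocusInterval] = []
    gene_locations: list[GeneLocation] = []
    locus_span = 1_000_000
    gene_width = 20_000
    for li, block in enumerate(locus_blocks):
        name = f"LOCUS{li + 1}"
        start = li * (locus_span + 200_000)
        loci.append(LocusInterval(name, "chrS", start, start + locus_span))
        step = locus_span // (len(block) + 1)
        for gi, g in enumerate(block):
            gs = start + (gi + 1) * step
            strand = "+" if (gi % 2 == 0) else "-"
            gene_locations.append(GeneLocation(g, "chrS", gs, gs + gene_width, strand))
        causal = block[0]
        ct = cfg.cell_types[li % len(cfg.cell_types)]
        crows = [gene_idx[causal]]
        for org in cfg.organs:
            effects[crows, cond_idx[(ct, org)]] += cfg.marker_effect
        truth.planted_locus_causal[name] = (causal, ct)
        if cfg.marker_effect > 0:
            truth.planted_markers.setdefault(ct, set()).add(causal)

    # -- assemble the log2 matrix and linear intensities --------------------
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    samples: list[SampleDescriptor] = []
    cols = []
    for (ct, org), rep in product(conditions, range(1, cfg.n_replicates + 1)):
        sid = f"{ct[0].upper()}{org[0].upper()}{rep}"
        samples.append(SampleDescriptor(sid, ct, org, rep, genotype="wt"))
        noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
        cols.append(baseline + effects[:, cond_idx[(ct, org)]] + noise)
    log2 = np.column_stack(cols)
    linear = np.power(2.0, log2)
    detection = 1.0 / (1.0 + np.exp(cfg.detection_a * (log2 - cfg.detection_b)))

    values = pd.DataFrame(linear, index=genes, columns=[s.sample_id for s in samples])
    detection_df = pd.DataFrame(detection, index=genes, columns=values.columns)
    matrix = ExpressionMatrix(
        values=values,
        samples=samples,
        probe_to_gene={g: g for g in genes},
        detection_p=detection_df,
        scale="linear",
    )

    # -- promoters with the planted motif -----------------------------------
    length = cfg.promoter_upstream + cfg.promoter_downstream
    seqs = _random_sequences(rng, cfg.n_genes, length)
    consensus = cfg.motif_consensus
    k = len(consensus)
    sensory_markers = truth.planted_markers.get("sensory", set())
    truth.planted_motif = consensus
    promoters: dict[str, str] = {}
    for g, seq in zip(genes, seqs):
        rate = cfg.motif_target_rate if g in sensory_markers else cfg.motif_background_rate
        if rng.random() < rate:
            off = int(rng.integers(0, length - k + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            word = consensus if strand == "+" else reverse_complement(consensus)
            seq = seq[:off] + word + seq[off + k:]
            truth.planted_motif_sites.setdefault(g, []).append((off, strand))
        promoters[g] = seq
    promoter_set = PromoterSet(sequences=promoters, upstream=cfg.promoter_upstream,
                               downstream=cfg.promoter_downstream)

    # -- interaction network -------------------------------------------------
    other = [g for g in genes if g not in truth.planted_module]
    n_extra = max(cfg.network_genes - cfg.module_size, 0)
    extra = list(rng.choice(other, size=min(n_extra, len(other)), replace=False))
    nodes = sorted(set(module_genes) | set(extra))
    network = nx.Graph()
    network.add_nodes_from(nodes)
    nodes_arr = np.array(nodes)
    n_nodes = len(nodes_arr)
    iu, ju = np.triu_indices(n_nodes, k=1)
    mask = rng.random(iu.size) < cfg.network_edge_prob
    for a, b in zip(nodes_arr[iu[mask]], nodes_arr[ju[mask]]):
        network.add_edge(a, b)
    mod = sorted(module_genes)
    for i in range(len(mod)):
        for j in range(i + 1, len(mod)):
            if rng.random() < cfg.module_edge_prob:
                network.add_edge(mod[i], mod[j])
    for i in range(len(mod) - 1):  # guarantee the planted module is connected
        network.add_edge(mod[i], mod[i + 1])

    target_coll = GeneSetCollection(
        [GeneSet(name, f"predicted targets of {name}", tuple(block))
         for name, block in targets.items()],
        universe=genes,
    )
    return SyntheticDataset(
        matrix=matrix,
        promoters=promoter_set,
        mirna_targets=target_coll,
        network=network,
        loci=loci,
        gene_locations=gene_locations,
        truth=truth,
        config=cfg,
    )


def generate_twirler(config: SimulationConfig, truth: SyntheticTruth) -> ExpressionMatrix:
    """Generate single-replicate mutant arrays (genotype x compartment x organ).

    Mirrors the mutant profiling design: one array per condition, CD326
    sorting into epithelial (pos) and non-epithelial (neg) compartments.  In
    mutant CD326-negative samples a fraction ``twirler_fraction`` of the
    epithelial (sensory) marker genes gains ``twirler_shift`` log2 units for
    homozygotes (both organs), a weaker shift for heterozygote vestibule and
    none for heterozygote cochlea; mesenchymal markers move down
    proportionally.  The de-repressed/down-regulated gene sets are recorded
    on ``truth``.
    """
    cfg = config
    if "sensory" not in truth.planted_markers or not truth.planted_markers["sensory"]:
        raise ConfigError("truth lacks the epithelial (sensory) marker set")
    rng = np.random.default_rng(cfg.seed + 104729)  # independent stream
    genes = _gene_ids(cfg.n_genes)
    gene_idx = {g: i for i, g in enumerate(genes)}

    epithelial = sorted(truth.planted_markers["sensory"])
    mesenchymal = sorted(truth.planted_markers.get("mesenchymal", set()))
    n_de = int(round(cfg.twirler_fraction * len(epithelial)))
    derep = list(rng.choice(epithelial, size=n_de, replace=False)) if n_de else []
    n_dn = int(round(cfg.twirler_fraction * len(mesenchymal)))
    down = list(rng.choice(mesenchymal, size=n_dn, replace=False)) if n_dn else []
    truth.twirler_derepressed = set(derep)
    truth.twirler_downregulated = set(down)

    epi_rows = [gene_idx[g] for g in epithelial]
    derep_rows = [gene_idx[g] for g in derep]
    down_rows = [gene_idx[g] for g in down]

    # genotype/organ-dependent magnitude of the de-repression
    def epi_shift(genotype: str, organ: str) -> float:
        if genotype == "Tw_hom":
            return cfg.twirler_shift
        if genotype == "Tw_het" and organ == "vestibule":
            return cfg.twirler_het_vestibule_shift
        return 0.0

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    samples: list[SampleDescriptor] = []
    cols = []
    for genotype in ("wt", "Tw_het", "Tw_hom"):
        for organ in cfg.organs:
            for compartment in ("CD326pos", "CD326neg"):
                sid = f"{genotype}_{organ}_{compartment}"
                samples.append(SampleDescriptor(
                    sid, "mixed", organ, 1, genotype=genotype, compartment=compartment))
                log2 = baseline + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
                if compartment == "CD326pos":
                    log2[epi_rows] += cfg.compartment_effect
                else:
                    d = epi_shift(genotype, organ)
                    if d:
                        log2[derep_rows] += d
                        log2[down_rows] += cfg.twirler_mesenchymal_shift * (d / cfg.twirler_shift)
                cols.append(np.power(2.0, log2))
    values = pd.DataFrame(np.column_stack(cols), index=genes,
                          columns=[s.sample_id for s in samples])
    return ExpressionMatrix(values=values, samples=samples,
                            probe_to_gene={g: g for g in genes}, scale="linear")
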