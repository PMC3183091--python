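"""Expression-interaction modules and disease-locus candidate ranking.

First find connected subnetworks of co-expressed genes in the interaction
graph (greedy seed-and-extend over pairwise Pearson similarity of condition
patterns), then use markers and module membership to rank candidate genes
inside uncloned disease-locus intervals.
"""

from earlens.simulate import SimulationConfig, generate_dataset
from earlens.preprocess import (filter_detected, quantile_normalize,
                                log2_transform, collapse_probes, condition_means)
from earlens.signatures import define_markers
from earlens.netmod import similarity_matrix, find_modules
from earlens.loci import prioritize

ds = generate_dataset(SimulationConfig(n_genes=4000, markers_per_type=150,
                                       targets_per_family=120, seed=1))
filtered = filter_detected(ds.matrix)
gene_linear = collapse_probes(quantile_normalize(filtered))
gene_log2 = collapse_probes(log2_transform(quantile_normalize(filtered)))
profile = condition_means(gene_log2)

sim = similarity_matrix(profile, genes=sorted(ds.network.nodes))
modules = find_modules(ds.network, sim)
print(f"modules found: {len(modules)}")
for m in modules:
    overlap = len(set(m.genes) & ds.truth.planted_module)
    print(f"  front={len(m.front)} back={len(m.back)} "
          f"mean-similarity score={m.score:.3f} "
          f"overlap with planted module: {overlap}/{len(ds.truth.planted_module)}")

markers = define_markers(gene_linear)
expressed = set(gene_linear.probe_ids)
print("\nlocus candidate ranking (expected cell type from the planted truth):")
for locus in ds.loci:
    causal, ct = ds.truth.planted_locus_causal[locus.name]
    rep = prioritize(locus, ds.gene_locations, expressed, markers,
                     modules=modules, expected_cell_type=ct)
    top = rep.top(1)[0] if len(rep.ranking) else "-"
    flag = "<- causal" if top == causal else ""
    print(f"  {locus.name}: {len(rep.genes_in_locus)} genes, "
          f"{len(rep.expressed)} expressed, top candidate {top} {flag}")
# The planted cell-type-selective gene tops each locus, mirroring how a
# neuronal-selective candidate can be prioritized in an auditory-neuropathy
# linkage interval.
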