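"""Call cell-type marker genes with the 50%-higher linear-scale rule.

A gene is a marker of a cell type when its *minimum* intensity over that
type's samples (both organs) is at least 1.5x its *maximum* over every
other cell type's samples.  The rule is deliberately stringent: for any
ratio above 1, marker sets are disjoint by construction.
"""

from earlens.simulate import SimulationConfig, generate_dataset
from earlens.preprocess import filter_detected, quantile_normalize, collapse_probes
from earlens.signatures import define_markers

ds = generate_dataset(SimulationConfig(n_genes=4000, markers_per_type=150,
                                       targets_per_family=120, seed=1))
gene_linear = collapse_probes(quantile_normalize(filter_detected(ds.matrix)))
markers = define_markers(gene_linear, ratio=1.5)

called = markers.as_dict()
for ct, genes in sorted(called.items()):
    truth = ds.truth.planted_markers.get(ct, set())
    tp = len(genes & truth)
    print(f"{ct:12s}: {len(genes):4d} markers called, {tp} of them planted "
          f"(precision {tp / len(genes):.3f})")
top = markers.table.dropna(subset=["cell_type"]).nlargest(3, "margin")
print("\nlargest margins (min in-type / max out-of-type, linear scale):")
print(top.to_string(float_format=lambda v: f"{v:.2f}"))
# Margins well above 1.5 mean the marker separation is robust, not boundary.
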