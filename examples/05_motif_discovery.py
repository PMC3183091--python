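"""De novo promoter motif discovery over marker-gene promoters.

Canonical k-mers (a word and its reverse complement collapsed) are scored
by the hypergeometric upper tail of promoter presence in a marker set
versus the full expressed-promoter universe, Bonferroni-corrected over all
observed k-mers.  The top seed is expanded into a position weight matrix.
"""

from earlens.io import GeneSet, GeneSetCollection
from earlens.simulate import SimulationConfig, generate_dataset
from earlens.motifs import discover

ds = generate_dataset(SimulationConfig(n_genes=3000, markers_per_type=150,
                                       targets_per_family=100, seed=1))
marker_coll = GeneSetCollection(
    [GeneSet(ct, f"{ct} markers", tuple(sorted(genes)))
     for ct, genes in ds.truth.planted_markers.items()],
    universe=ds.matrix.probe_ids)

results = discover(marker_coll, ds.promoters, k_range=(8,), alpha=1e-4)
for set_name, motifs in sorted(results.items()):
    best = motifs[0]
    tag = "significant" if best.significant else "NS (best seed shown)"
    print(f"{set_name:12s}: top 8-mer {best.seed.kmer}  "
          f"p_corrected = {best.seed.p_corrected:.2e}  [{tag}]  "
          f"{best.seed.k_t}/{best.seed.n} target promoters hit")

best = results["sensory"][0]
print(f"\nplanted consensus: {ds.truth.planted_motif}")
print("PWM consensus of recovered motif:", best.consensus)
print("information content per position (bits):",
      [round(float(x), 2) for x in best.information_content])
print("\nMEME block:\n" + best.to_meme(name="sensory_motif"))
# Only the sensory marker set carries a planted motif; the other sets'
# best seeds stay above the corrected alpha, as they should.
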