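"""Mutant-vs-wild-type de-repression of epithelial genes.

Single mutant and control arrays (sorted CD326-negative, i.e. the
non-epithelial compartment) are jointly quantile-normalized and contrasted
per gene.  Genes are sorted by log2 fold change and the epithelial marker
set's positions form a barcode; a Wilcoxon rank-sum of marker fold changes
against the rest quantifies the de-repression.  Candidate direct repressor
targets are the up-shifted markers whose promoters carry the repressor's
binding motif.
"""

from earlens.io import GeneSet
from earlens.simulate import SimulationConfig, generate_dataset, generate_twirler
from earlens.enrich import genotype_contrast, rank_set_test, zeb1_target_candidates
from earlens.motifs import find_sites

cfg = SimulationConfig(n_genes=6000, markers_per_type=200,
                       targets_per_family=150, seed=1)
ds = generate_dataset(cfg)
tw = generate_twirler(cfg, ds.truth)

mut = tw.subset_samples(["Tw_hom_cochlea_CD326neg", "Tw_hom_vestibule_CD326neg"])
ctl = tw.subset_samples(["wt_cochlea_CD326neg", "wt_vestibule_CD326neg"])
fc = genotype_contrast(mut, ctl)

epi = GeneSet("epithelial", "", tuple(sorted(ds.truth.planted_markers["sensory"])))
mes = GeneSet("mesenchymal", "", tuple(sorted(ds.truth.planted_markers["mesenchymal"])))
r_epi, r_mes = rank_set_test(fc, epi), rank_set_test(fc, mes)
print(f"epithelial markers:  direction {r_epi.direction}, p = {r_epi.p:.2e} "
      f"(elevated in mutant non-epithelial cells -> de-repression)")
print(f"mesenchymal markers: direction {r_mes.direction}, p = {r_mes.p:.2e} "
      f"(relative loss of mesenchymal identity)")
print(f"first 10 barcode positions of epithelial markers in the sorted list: "
      f"{r_epi.barcode[:10]}")

hits = {g for g, _, _ in find_sites(ds.truth.planted_motif, ds.promoters)}
cand = zeb1_target_candidates(fc, epi, hits, fc_threshold=1.0)
truth = ds.truth.twirler_derepressed & set(ds.truth.planted_motif_sites)
prec = len(set(cand["gene"]) & truth) / len(cand)
print(f"\ncandidate direct repressor targets: {len(cand)} "
      f"(fold change >= 1 log2 AND motif in promoter), precision {prec:.2f}")
print(cand.head(5).to_string(index=False, float_format=lambda v: f"{v:.2f}"))
# The heterozygote shows the same shift only in the vestibule (weaker), and
# none in the cochlea - the graded genotype-phenotype pattern.
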