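# Methods

This note documents the statistical procedures implemented in `earlens`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generator does and does not emulate.

## Study design and preprocessing

The pipeline assumes a balanced full factorial of sorted cell populations:
`a` cell types × `b` organs × `r` replicates (default 4 × 2 × 3 = 24
arrays), with linear-scale intensities and per-measurement detection
p-values.  The fixed stage order is:

1. **Detection filter** — keep probes with detection p < 0.01 (strict) in
   ≥ 2 samples.  Idempotent; order-preserving.
2. **Quantile normalization** on linear intensities: each column's sorted
   values are replaced by the cross-column mean of sorted values at that
   rank.  Ties within a column receive the mean of their tied reference
   quantiles, so the map is rank-preserving and all columns share one
   value multiset afterwards.  Normalizing before the log transform
   follows common bead-array practice; the choice matters little for the
   rank-based downstream tests.
3. **log2(x + 1)** — the +1 offset keeps zero intensities finite and is
   negligible at signal-range intensities (2⁸ and above).
4. **Probe→gene collapse** — per gene, the probe with the highest mean
   intensity across samples is kept (ties by probe id).  Max-mean rather
   than averaging preserves the dynamic range of the best-responding
   probe; the mapping used is recorded in the output matrix.
5. **Condition means** — replicate averages per (cell type, organ); the
   8-column gene × condition profile is the substrate for miRNA activity,
   clustering, module similarity and factor cross-checks.

## Differential expression

Per gene, the classical balanced two-way fixed-effects decomposition:
SS_cell, SS_organ, SS_interaction, SS_error with df (a−1), (b−1),
(a−1)(b−1), ab(r−1); F = MS_factor / MS_error, p from the F distribution.
A gene is differential when the smallest of the three p-values is below
10⁻⁵; Benjamini–Hochberg q-values over that minimum p are reported
alongside (flag threshold 0.01).  Genes with zero residual variance are
flagged degenerate: p = 1 when the factor sum of squares is also ~0 (flat
gene), p = 0 otherwise.  The ANOVA runs on log2 values; unbalanced designs
are rejected rather than approximated.  The implementation is validated
against an independent sums-of-squares route (statsmodels `anova_lm`) to
1e-8 on the F statistics.

## Sample dendrogram and gene clusters

Samples are agglomerated with average linkage under 1 − Pearson distance;
constant sample vectors are rejected with a pointer to Euclidean distance.
Gene patterns (condition means standardized to mean 0, population SD 1;
constant rows dropped) are clustered by k-means, best inertia over 20
k-means++ restarts at a fixed seed; each cluster is summarized by its mean
pattern ± SD.  k defaults to 8 and is configurable — the appropriate k
depends on how many distinct cell-type/organ patterns the data hold.

## Marker rule

A gene is a marker of cell type t iff min over t's samples (both organs)
≥ ratio × max over every other cell type's samples, on the **linear**
scale ("50% higher" is a linear statement; ratio default 1.5, boundary
inclusive).  Comparing the in-type minimum against the out-of-type maximum
is the most stringent reading of "higher than the rest of the samples"; it
guarantees disjoint marker sets for any ratio > 1 and makes the rule
invariant to global rescaling.  The margin (min_in / max_out) is reported
per marker.

## miRNA activity

Relative levels r_gc = x_gc − mean_c x_g· (log2) are computed on condition
means, not per-replicate samples — activity is a property of a cell
population, and condition means are the stable summary.  For each target
set and condition, a two-sided Wilcoxon rank-sum compares target relative
levels against all remaining genes; exact enumeration when both groups
have ≤ 25 members, tie-corrected normal approximation otherwise.
Direction is the sign of the median difference; significance is p ≤ 10⁻⁵
(the grid's NS cut), with raw p retained.  Sets with fewer than 20
expressed targets are flagged untested — below that the normal
approximation and the biological premise (dozens of targets) both fray.

A caveat inherent to row-centering: a genuine depletion in some conditions
reappears as a small opposite shift (the removed row mean) in all other
conditions, which a large target set can render nominally significant.
Interpreting the grid therefore focuses on the strong primary signals; the
weak mirror-image calls in the remaining conditions are an arithmetic echo,
not evidence of activity there.

## Motif discovery

Promoter windows cover −1000..+200 nt around the TSS, oriented 5′→3′
toward the gene (minus-strand genes take the reverse complement of the
mirrored slice).  Promoters with > 20% N are dropped; windows containing N
are skipped.  A word and its reverse complement collapse to one canonical
k-mer (lexicographic minimum), so scanning is strand-agnostic, and a
promoter counts once regardless of instance multiplicity — this makes the
score robust to local repeats.  Enrichment of a canonical k-mer in a
marker set's promoters versus the expressed-promoter universe is the
exact hypergeometric upper tail; correction is Bonferroni over the
canonical k-mers actually observed in the universe (pooled across k when
scanning a k range).  Bonferroni rather than BH because motif discovery
makes a small number of discovery-style claims against massive
multiplicity, and family-wise control is the defensible guarantee there.
Significant seeds (α = 10⁻⁴) are expanded into PWMs by stacking exact hit
sites (reverse-complement hits re-oriented), adding a 0.5 pseudocount and
normalizing; information content is 2 − column entropy.  PWMs export in
minimal MEME text.  The scan is a deliberately simple, fully specified
stand-in for heavier motif optimizers: no seed merging across lengths, no
degenerate-position optimization, no localization scores.

## Set enrichment and the mutant contrast

Over-representation of a query set in annotation sets is the exact
hypergeometric tail (computed via the survival function in log space;
validated against full enumeration for N ≤ 12 at 1e-10 relative), with BH
q across the tested sets and fold = (k/n)/(K/N).  Cluster bias of a
special gene list toward focal clusters is the same tail with the
focal-cluster union as the annotation and all clustered genes as the
universe.

Mutant-vs-control contrasts are built for single arrays per group: both
matrices are quantile-normalized **together** (so array-wide intensity
differences cannot masquerade as fold change), log-transformed, and
subtracted per gene.  With no replication there is deliberately no
per-gene p-value; inference is set-level only, via the rank test: genes
sorted by fold change, marker positions reported as a barcode, and a
two-sided Wilcoxon rank-sum of marker fold changes versus the rest
(invariant to monotone transforms of the fold changes).  Candidate direct
repressor targets are markers with fold change ≥ 1 log2 *and* a motif hit
in their promoter, sorted by fold change; the 1-log2 cutoff is a
conventional two-fold bar, configurable.

## Expression-interaction modules

Pairwise Pearson similarity of standardized condition patterns feeds a
deterministic greedy seed-and-extend over the interaction graph: seeds are
edges with similarity ≥ 0.8 (best first), and each step adds the neighbor
with the largest positive gain of the objective

    Σ over front pairs of (s_ij − τ)  −  λ·|back|,        τ = seed threshold

so an addition is profitable exactly when its mean similarity to the
current front exceeds τ.  (A raw mean-pairwise objective stalls
immediately — any addition below the current mean lowers the mean — which
is why the threshold-shifted form is used for the gain; the reported
module score is still mean pairwise similarity minus λ·|back|.)  Genes
whose mean similarity to the front falls below τ/2 may enter only as
"back" connectors, and only when they bridge components or open a
profitable front addition within two steps; λ = 0.05 keeps connectors
sparse.  Modules stop at 60 genes or no positive gain, need ≥ 8 genes to
be reported, and claimed connectivity is certified by a spanning tree and
re-checked by independent BFS in the tests.  This is an explicit,
testable approximation of probabilistic module finders that use annealing
over a likelihood-based similarity model; it trades their flexibility for
determinism.

## Locus candidates

Genes overlap a locus under half-open interval arithmetic (any overlap).
Ranking tiers: (1) selectively expressed in the expected cell type —
either the strict marker rule or, optionally, relative-level dominance of
≥ 1 log2 over every other cell type (the looser reading matters when the
strict rule finds nothing); (2) member of an expression-interaction module
that also contains a known disease gene; (3) expressed at all.  Ties break
by marker margin then gene id, giving a deterministic total order, and a
verification pass recomputes every containment claim from the raw inputs.

## Synthetic data

The generator's defaults are the study conditions: 12 000 genes, 4 × 2 × 3
design, gene baselines ~ Normal(8, 1.5) log2, i.i.d. Gaussian noise
σ = 0.25, 300 markers per cell type at +2 log2, an organ effect of 1 log2
confined to sensory markers (half per organ, so the dendrogram splits
sensory samples by organ below the cell-type partition), 4 miRNA families
× 250 targets with one active family (−0.6 log2 in both sensory
conditions, +0.4 in both mesenchymal), an 8-mer motif (consensus
CACCTGTC, an E-box-like word) planted at rate 0.4 in sensory-marker
promoters and 0.04 elsewhere on a uniformly random strand and offset,
1200-nt promoters, a 25-gene module with a shared profile (scale 1.2,
per-gene amplitude 0.8–1.2) wired at internal edge probability 0.6 into a
400-node background network (edge probability 0.01), four 12-gene loci
with one cell-type-selective causal gene each, and detection
p = 1/(1 + exp(3·(log2 x − 6))) — a logistic dropout that removes dim
genes much as bead-level detection calls do.  Mutant arrays are single
replicates per genotype × organ × compartment; 60% of epithelial markers
gain +1.5 log2 in homozygous-mutant non-epithelial samples (+0.75 in
heterozygote vestibule, 0 in heterozygote cochlea) and mesenchymal
markers shift down proportionally (−1.0 at full strength).  Values not
fixed by the design (organ effect, module profile scale, network size,
locus count, mutant shift magnitudes) were chosen once as realistic array
effect sizes and are exposed on `SimulationConfig`.

What the generator does **not** emulate: probe-level bead variance,
spatial artifacts, background fluorescence, cross-hybridization,
batch/chip effects, correlated noise between genes, or realistic genomic
sequence composition (promoters are uniform random DNA).  Passing the
recovery tests therefore demonstrates that the statistics detect the
effects they target at realistic effect sizes and sample counts — not
that the pipeline is robust to every artifact of physical arrays.

## Numerical choices and problem sizes

Exact Wilcoxon enumeration switches to the tie-corrected normal
approximation above group size 25.  Hypergeometric tails go through the
log-space survival function.  k-means ties and all greedy iteration
orders are fixed (sorted gene ids), so every stage is deterministic given
the seed; the pipeline fans one global seed out to stages by fixed
offsets.  The test suite runs the full 12 000-gene design for recovery
checks, the motif scan at 300 target vs 5 300 universe promoters of
1 200 nt, the ANOVA null at 10 000 genes, and the motif family-wise-error
null at a reduced 400-promoter × 300-nt scale over 100 simulations —
family-wise error control of a Bonferroni-corrected scan does not depend
on the problem size, and the reduced scale keeps the null study quick.

## Known limitations

- The ANOVA requires a balanced design; missing arrays must be handled
  upstream.
- Marker calling with min-vs-max is sensitive to a single outlier array
  (one bad in-type sample can veto a true marker); the stringency is the
  point, but a rank-based variant would be more robust.
- Motif attribution (matching a discovered PWM to a transcription-factor
  family) is manual; no PWM database comparison is included.
- The module finder is greedy: it cannot split a seed that absorbed two
  overlapping true modules, and module boundaries depend on the seed
  threshold.
- Single-array mutant contrasts support set-level claims only; per-gene
  fold changes in the candidate table are descriptive.
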