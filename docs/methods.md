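# Methods

This note documents the models, parameters and design choices behind
`abcatlas`, in the order the pipeline runs them.

## Quantification and quality control

Molecule counts are defined as the number of **distinct UMIs** observed per
(cell, gene); PCR duplicates (identical UMI within a cell/gene pair)
collapse to one molecule. Malformed read rows are fatal by default, or
dropped with their indices reported when `strict=False`.

Cell retention applies two independent rule families:

- **Mapping rate** (supplied as opaque per-cell metadata, since its exact
  definition depends on the upstream aligner): a cell is discarded when its
  rate is *strictly below* its lineage family's threshold — 0.10 for HSPC
  and monocyte families, 0.05 for B/NK/neutrophil/erythroid, 0.025 for T.
  The label→family map and the thresholds are editable configuration; an
  unmappable cell-type label is a fatal error rather than a silent pass.
- **Detection**: strictly *more than* `min_coding` protein-coding genes
  (default 1000) and, separately, strictly more than `min_lnc` lncRNAs
  (default 500) must be detected. Because the two biotype matrices are
  analysed separately, the coding-retained and lncRNA-retained cell sets
  are tracked separately and generally differ.

Both rules are order-independent and idempotent, so re-filtering a filtered
matrix is a no-op. Normalization is `log2(TPM/10 + 1)` with TPM computed
per cell *within the biotype matrix being normalized* (each biotype sums to
10^6 before the transform); joint normalization is available by normalizing
before splitting. A zero-total cell is a fatal error — QC must run first.

For synthetic runs the pipeline scales the detection cut-offs to the toy
gene universe (600 of 2000 coding genes, 150 of 1000 lncRNAs) so they play
the same proportional role they do against a full genome annotation; the
absolute defaults above remain on `qc_filter` itself.

## Differential expression and signatures

The Wilcoxon rank-sum test is implemented in the package (it is the
workhorse of every comparison): exact enumeration of the U distribution
over all assignments of the pooled midranks for total sample sizes ≤ 12
(valid with ties), and otherwise a normal approximation with midranks,
tie-corrected variance and a 0.5 continuity correction. Two-sided exact
p-values use the `2·min(P≤, P≥)` convention, matching the exact
Mann–Whitney distribution. A vectorized one-vs-rest variant shares one
pooled ranking across all cell types, since rank sums differ only in the
group membership.

Signature calling is one-vs-rest per type on the normalized matrix, with
Benjamini–Hochberg adjustment within each type's gene family. Defaults:
`q ≤ 0.05`, `log2FC ≥ 1`, detected in ≥ 25% of the type's cells; a top-N
mode (ranked by q then fold change, positive fold only) is available where
a fixed signature size is preferred. Fold changes are computed on de-logged
means (`2^x − 1`, i.e. TPM/10) with a 1e-9 pseudocount — stable for sparse
data and exactly zero for identical groups. Types with fewer than 3 cells
are skipped with a warning; fewer than two eligible types is an error.

Pairwise DEG counts between all type pairs use the same test with
`|log2FC| ≥ 1`; the matrix is symmetric with a zero diagonal by
construction. "Scaled" DEG matrices divide by the matrix maximum (a
min–max variant is provided); coding/lncRNA agreement is the Spearman
correlation over off-diagonal entries, with a composite display matrix
carrying coding counts below and lncRNA counts above the diagonal.

## lncRNA characterization

- **Specificity.** For gene g, the per-type mean expression vector is
  normalized to a probability profile e_g and scored against each one-hot
  type profile δ_t as `1 − √(JSD(e_g, δ_t))` with the Jensen–Shannon
  divergence in log base 2 (bounded [0, 1]; a gene expressed in exactly
  one type scores 1 there). Genes with zero mean everywhere are NA.
- **Adjacency.** A coding gene neighbors a lncRNA when both lie on the
  same chromosome with interval gap strictly below 5 kb, where the gap
  between 0-based half-open intervals is `max(0, max(starts) − min(ends))`
  (0 when overlapping). The gap is measured between gene-body hulls, not
  TSS-to-TSS, and strand is ignored; all three choices are configurable.
  The per-type adjacency proportion pairs a type's signature lncRNAs with
  that type's signature coding genes (cross-type matching behind a flag);
  types with no signature lncRNAs are NA.
- **Conservation.** Gene-level conservation scores (e.g. PhastCons
  averaged over the gene body) are compared between signature and
  background lncRNAs with the one-sided rank-sum test. The background is
  all expressed non-signature lncRNAs; the two sets must be disjoint.
- **Neighbor overlap.** The overlap between {coding neighbors of signature
  lncRNAs} and a reference signature set is tested with the upper-tail
  hypergeometric distribution over a stated gene universe.

## Regulon activity

Regulons (a TF plus its target set, TF always included; minimum 5
resolvable targets, configurable) are **inputs** — network inference and
motif pruning are upstream of this package. Per cell, genes are ranked by
descending expression with ties broken by the fixed gene order (making
scores deterministic and invariant under monotone transforms); with
`X = floor(0.05 · n_genes)`, the RAS is the mean of the recovery curve
`r(k) = |targets among top k| / |targets|` over `k = 1..X`. A random
target set scores about `(X+1)/(2·n_genes)`; a regulon whose targets crowd
the top of the ranking approaches 1.

Binarization is per regulon by deterministic 1-D two-means, initialized at
the 10th/90th percentiles (falling back to min/max when those coincide,
e.g. a single active cell); the threshold is the midpoint of the final
centers and a cell is "on" strictly above it. Values are pre-sorted so the
result is independent of cell order; constant columns are dropped with a
warning. Note that a regulon whose RAS distribution is unimodal (e.g. a
housekeeping program active everywhere) has no meaningful two-means split
and its binary calls should not be over-interpreted — on/off state logic
is designed for bimodal lineage programs.

Cluster-level states take a supplied cell partition (immunophenotypes,
lineage families, or any clustering; this package does not re-implement
graph clustering): a regulon is on in a cluster when ≥ 50% of its cells
are on, and "cluster-specific" when it is on there and on in fewer than
`max_other_on` (default 2) other clusters. Novel regulons are those on in
at least one cluster whose TF is absent from the canonical list; an
editable compilation of widely reported hematopoietic TFs ships under
`resources/canonical_tfs.txt`, and synthetic runs use the generator's own
canonical record.

## Cell-type projection

The reference holds per-type centroids over features chosen round-robin
from the per-type q-value rankings of the one-vs-rest test (default 500
features; all genes, with a warning, when the matrix is smaller).
Centroids are per-type **means**. The design brief favored medians for
outlier robustness, but at the scale this package targets medians fail
structurally: with counts around 1 and heavy dropout, the per-gene median
over a few dozen cells flips between 0 and the detected log level, so
centroid differences become noise — measured held-out accuracy collapsed
to 0.24–0.38 with medians versus ≈ 0.97 with means on the default
synthetic atlas. Means average dropout away and are kept.

Queries are assigned by cosine similarity over the shared features (≥ 50%
of the reference features required, else an error): the argmax centroid
when its similarity reaches the threshold (default 0.7, the established
unassignment default for cluster-centroid projection), else UNASSIGNED.
Exact ties break by the reference's fixed type order and are reported.
Self-projection accuracy uses stratified k-fold (default 5) with a seeded
shuffle; types smaller than the fold count are evaluated leave-one-out
with a warning. UNASSIGNED counts as incorrect — the stricter convention
for "correctly annotated".

## Synthetic atlas

The generator emulates the study design at desk scale and records every
planted quantity in a `SimTruth` object:

- **Design**: 32 immunophenotypic labels in 7 lineage families, 50 cells
  per type from 21 donors (round-robin); B/NK/T subsets drawn from
  peripheral blood, the rest bone marrow. A planted fraction (default
  0.05) of cells receives a mapping rate strictly below its family
  threshold, the rest safely above.
- **Counts**: negative binomial per gene (gamma–Poisson, shared dispersion
  α = 0.3), gene base means lognormal (median 1.2, σ = 0.8; lncRNAs scaled
  by 0.5 to reflect their lower abundance), per-cell capture efficiency
  U(0.8, 1.2). Each type carries 10–40 planted coding signature genes
  (half as many lncRNAs) whose means are multiplied by 5 in that type —
  set sizes vary by type so the pairwise DEG structure has genuine
  variation for the concordance analysis, and densely enough that types
  are separable, mirroring the hundreds of DEGs real immunophenotypic
  types show. Reads are emitted one row per molecule with deterministic
  distinct UMIs plus a 10% duplicate rate, so UMI collapsing recovers the
  count matrix exactly.
- **Genome**: genes are laid out in well-separated placement units on one
  synthetic chromosome; exactly `round(0.6 · n_lnc)` lncRNAs sit at a gap
  drawn from U{0..4999} next to a coding partner (signature lncRNAs
  preferentially next to their own type's signature coding genes), and
  every other lncRNA is ≥ 5 kb from every coding gene. An explicit sizing
  error is raised when the genome length cannot host the layout.
- **Conservation**: Beta-distributed gene scores (concentration 8);
  lncRNA background mean 0.15, signature lncRNAs shifted up by 0.3,
  coding genes at 0.5.
- **Regulons**: one lineage regulon per family (targets = the family's
  planted coding signatures; TF = the first of them), three of which are
  withheld from the canonical list to plant "novel" calls; plus broad
  regulons over the highest-baseline genes and a silent regulon over the
  lowest-baseline genes (non-canonical but never activated, so novelty
  flagging must not fire on it).

What the generator does **not** emulate: doublets, ambient RNA, batch or
donor effects, gene length bias, correlated gene programs beyond the
planted signatures, or read sequences. Passing tests therefore demonstrate
that the implementations recover planted structure under a clean
negative-binomial world — they do not certify performance on real data,
where those nuisances dominate.

## Problem sizes and determinism

The default synthetic design (1600 cells × 3000 genes) runs the full
pipeline — UMI expansion and collapsing included — in about a minute on
one CPU; the test suite uses this design for recovery checks and a reduced
8-type/900-gene design for end-to-end and multi-seed checks. One seed
drives every stochastic stage through a single `numpy` Generator, and the
pipeline summary is byte-identical across runs with the same config and
seed (JSON keys sorted, no parallel nondeterminism).

## Known limitations

- Signature thresholds (q, fold change, detection fraction) are common
  practice rather than uniquely determined; both threshold and top-N modes
  are exposed because the "right" signature definition is
  context-dependent.
- The BH adjustment treats each cell type's scan as its own family;
  a global correction across types would be more conservative.
- Two-means binarization assumes bimodal RAS; unimodal regulons get an
  arbitrary split (see above).
- The hypergeometric overlap test assumes neighbors are an unbiased draw
  from the stated universe; genomic clustering of genes violates this
  mildly.
- Centroid projection carries no rejection option other than the cosine
  threshold; novel cell types in a query are assigned to the nearest
  reference type whenever similarity clears it.
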