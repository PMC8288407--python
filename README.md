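# abcatlas

Analysis toolkit for a single-cell transcriptional atlas of human blood
cells: deep plate-based (STRT-seq-style) profiles of FACS-sorted
immunophenotypic cell types — hematopoietic stem/progenitor cells through
mature B, NK, T, monocyte, neutrophil and erythroid populations — analysed
jointly through protein-coding genes and long noncoding RNAs (lncRNAs).

The package implements the downstream analysis layer that sits on top of
alignment and gene counting:

- **Quantification & QC** — reads are collapsed to molecules by counting
  *distinct UMIs* per (cell, gene); cells are retained only when their
  mapping rate clears a lineage-specific floor (10% for HSPCs/monocytes,
  5% for B/NK/neutrophil/erythroid cells, 2.5% for T cells) and when more
  than 1000 protein-coding genes (respectively 500 lncRNAs) are detected.
  Expression is normalized to `log2(TPM/10 + 1)`.
- **Signature calling** — per cell type, one-vs-rest Wilcoxon rank-sum
  tests (implemented here, with exact enumeration for small samples and a
  tie/continuity-corrected normal approximation otherwise) with
  Benjamini–Hochberg FDR control; a gene is a signature when
  `q ≤ 0.05`, `log2FC ≥ 1` and it is detected in ≥ 25% of the type's
  cells. Pairwise DEG-count matrices summarize the transcriptional
  distances between all type pairs, and a Spearman correlation over their
  off-diagonal entries quantifies the coding/lncRNA agreement.
- **lncRNA characterization** — cell specificity is scored against the
  one-hot ideal with the Jensen–Shannon divergence,
  `score(g, t) = 1 − √(JSD(e_g, δ_t))` in log base 2; protein-coding
  neighbors within 5 kb of each lncRNA are scanned along the genome
  (strictly `gap < 5000` bp on 0-based half-open intervals); conservation
  of signature versus background lncRNAs is compared with a one-sided
  rank-sum test, and neighbor/reference-set overlaps with a
  hypergeometric tail.
- **Regulon activity** — given transcription-factor target sets, each
  cell's regulon activity score (RAS) is the area under the target
  recovery curve within the top 5% of the cell's expression ranking;
  scores are binarized by a deterministic two-means split and summarized
  into cluster-level on/off states; activated regulons whose TF is absent
  from a canonical list are flagged novel.
- **Cell-type projection** — a reference of per-type mean centroids over
  signature-ranked features assigns query cells by cosine similarity
  (UNASSIGNED below 0.7), and stratified k-fold self-projection estimates
  annotation accuracy.
- **Synthetic atlas** — a fully ground-truthed generator (negative
  binomial counts with planted fold changes, planted lncRNA/coding
  adjacency, shifted conservation scores, planted regulon programs and QC
  failures) so every stage is testable without the study's raw data.

## Worked example

```python
import abcatlas as abc

atlas = abc.simulate_atlas(abc.AtlasConfig.small(), seed=0)   # 8 types, 900 genes
qc = abc.qc_filter(atlas.counts, min_coding=150, min_lnc=40)
norm_c = abc.normalize_log2tpm10(qc.coding)
norm_l = abc.normalize_log2tpm10(qc.lncrna)

sig_c = abc.find_signatures(norm_c)
sig_l = abc.find_signatures(norm_l)
adj = abc.adjacency_scan(atlas.annotation)
prop = abc.signature_adjacency_proportion(sig_l, sig_c, adj)
proj = abc.self_projection_accuracy(norm_c, seed=0)
```

Printing the QC summary, the top of the signature table and the headline
statistics gives, for seed 0:

```
retained: {'n_input': 240, 'n_removed_mapping_rate': 12, 'n_removed_low_coding': 0,
           'n_removed_low_lnc': 0, 'n_retained_coding': 228, 'n_retained_lncrna': 228}
signature calls: 160 coding, 84 lncRNA
cell_type  gene_id   log2fc            p            q  pct_in  pct_out
      HSC PCG00510 2.555847 6.937906e-16 1.762490e-13     1.0    0.540
      HSC PCG00165 2.401653 8.812449e-16 1.762490e-13     1.0    0.805
adjacency proportion (EarlyEry): 0.6
conservation: sig median 0.475 vs background 0.111, one-sided p = 2.40e-30
self-projection accuracy: 0.969
```

The 12 planted QC failures are exactly the 12 cells removed for low
mapping rate; the per-type adjacency proportion recovers the planted 0.6
lncRNA/coding coupling; signature lncRNAs carry the planted conservation
shift; and held-out cells project back onto their own type 97% of the
time.

The command line mirrors the library: `abcatlas simulate`, `abcatlas qc`,
`abcatlas signatures`, `abcatlas degmatrix`, `abcatlas lnc-adjacency`,
`abcatlas lnc-specificity`, `abcatlas lnc-conservation`, `abcatlas ras`,
`abcatlas regulon-states`, `abcatlas build-ref`, `abcatlas predict`,
`abcatlas self-accuracy` and `abcatlas run --config cfg.yaml` for the full
pipeline from one YAML config.

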