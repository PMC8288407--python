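"""lncRNA characterization: cell specificity, genomic adjacency, conservation.

Cell specificity of a gene is scored against the one-hot ideal with the
Jensen-Shannon divergence (base 2): the per-type mean expression profile is
normalized to a probability vector e_g and

    score(g, t) = 1 - sqrt( JSD(e_g, delta_t) )

so a gene expressed in exactly one type scores 1 there. Genomic adjacency
pairs each lncRNA with every protein-coding gene on the same chromosome at
a gap strictly below ``max_dist`` (default 5 kb), where the gap between two
0-based half-open intervals is max(0, max(starts) - min(ends)); overlapping
genes have gap 0. Strand is ignored.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModelSet
from .signatures import SignatureSet
from .stats import hypergeometric_overlap_test, rank_sum_test

DEFAULT_MAX_DIST = 5000


def _entropy_terms(p: np.ndarray) -> np.ndarray:
    """Elementwise -p*log2(p), with 0*log(0) = 0."""
    out = np.zeros_like(p, dtype=float)
    pos = p > 0
    out[pos] = -p[pos] * np.log2(p[pos])
    return out


def jsd(p: Sequence[float], q: Sequence[float], atol: float = 1e-9) -> float:
    """Jensen-Shannon divergence between two distributions, log base 2.

    JSD(p, q) = H((p+q)/2) - (H(p) + H(q))/2, bounded in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    for name, v in (("p", p), ("q", q)):
        if np.any(v < 0):
            raise ValueError(f"{name} has negative entries")
        if abs(v.sum() - 1.0) > atol:
            raise ValueError(f"{name} does not sum to 1 (got {v.sum():.12f})")
    m = (p + q) / 2.0
    value = _entropy_terms(m).sum() - (
        _entropy_terms(p).sum() + _entropy_terms(q).sum()
    ) / 2.0
    return float(min(max(value, 0.0), 1.0))


@dataclass
class SpecificityTable:
    """Per-gene, per-type specificity scores in [0, 1].

    ``scores`` is genes x cell types; ``max_score``/``top_type`` give the
    best score and where it is attained. Genes with zero mean expression
    everywhere carry NaN scores.
    """

    scores: pd.DataFrame
    max_score: pd.Series
    top_type: pd.Series

    def to_tsv(self, path: str | Path) -> None:
        out = self.scores.copy()
        out["max_score"] = self.max_score
        out["top_type"] = self.top_type
        out.to_csv(path, sep="\t")


def specificity_scores(
    norm: ad.AnnData, groupby: str = "cell_type"
) -> SpecificityTable:
    """JSD-based cell-specificity scores for every gene.

    The gene's mean expression per type is normalized to sum 1 and scored
    against each one-hot type profile as 1 - sqrt(JSD).
    """
    if groupby not in norm.obs:
        raise ValueError(f"norm.obs lacks column {groupby!r}")
    labels = norm.obs[groupby]
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need at least two cell types")
    expr = np.asarray(norm.X, dtype=float)
    means = np.vstack([
        expr[(labels == t).to_numpy()].mean(axis=0) for t in types
    ]).T  # genes x types
    totals = means.sum(axis=1)
    ok = totals > 0
    e = np.full_like(means, np.nan)
    e[ok] = means[ok] / totals[ok, None]

    # H(m_t) decomposes into shared terms plus the column-t correction, so
    # all one-hot comparisons are computed in one vectorized pass.
    half = np.where(np.isnan(e), np.nan, e / 2.0)
    h_half = _entropy_terms(np.nan_to_num(half))
    h_half[~ok] = 0.0
    shared = h_half.sum(axis=1)
    h_e = _entropy_terms(np.nan_to_num(e)).sum(axis=1)
    scores = np.full_like(means, np.nan)
    for t_idx in range(len(types)):
        bumped = _entropy_terms(np.nan_to_num(half[:, t_idx] + 0.5))
        h_m = shared - h_half[:, t_idx] + bumped
        div = np.clip(h_m - h_e / 2.0, 0.0, 1.0)
        scores[:, t_idx] = 1.0 - np.sqrt(div)
    scores[~ok] = np.nan

    frame = pd.DataFrame(scores, index=norm.var_names, columns=types)
    max_score = frame.max(axis=1)
    top_type = frame.fillna(-np.inf).idxmax(axis=1)
    top_type[~ok] = pd.NA
    return SpecificityTable(scores=frame, max_score=max_score, top_type=top_type)


@dataclass
class AdjacencyMap:
    """lncRNA -> nearby protein-coding genes with their gaps (bp)."""

    neighbors: dict[str, list[tuple[str, int]]]
    max_dist: int

    def __len__(self) -> int:
        return len(self.neighbors)

    def neighbors_of(self, lnc_id: str) -> list[tuple[str, int]]:
        return self.neighbors.get(lnc_id, [])

    def coding_neighbors(self, lnc_ids: Sequence[str] | None = None) -> set[str]:
        source = self.neighbors if lnc_ids is None else {
            l: self.neighbors[l] for l in lnc_ids if l in self.neighbors
        }
        return {coding for pairs in source.values() for coding, _ in pairs}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (lnc, coding, gap)
            for lnc, pairs in sorted(self.neighbors.items())
            for coding, gap in pairs
        ]
        return pd.DataFrame(rows, columns=["lncRNA_id", "coding_id", "gap_bp"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def interval_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Gap in bp between two 0-based half-open intervals (0 if overlapping)."""
    return max(0, max(start_a, start_b) - min(end_a, end_b))


def adjacency_scan(
    annotation: GeneModelSet, max_dist: int = DEFAULT_MAX_DIST
) -> AdjacencyMap:
    """Scan for protein-coding genes within ``max_dist`` of each lncRNA.

    A coding gene is a neighbor iff it lies on the same chromosome at a gap
    strictly below ``max_dist``; strand is ignored. Neighbors are reported
    sorted by gap then gene id.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    df = annotation.df
    coding = df[df["biotype"] == "coding"]
    lnc = df[df["biotype"] == "lncRNA"]
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in coding.groupby("chrom", observed=True):
        tree = IntervalTree()
        for gid, row in sub.iterrows():
            tree.addi(row["start"], row["end"], gid)
        trees[chrom] = tree

    neighbors: dict[str, list[tuple[str, int]]] = {}
    for gid, row in lnc.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        hits = []
        # coding overlaps (start - max_dist, end + max_dist) iff gap < max_dist
        for iv in tree.overlap(row["start"] - max_dist, row["end"] + max_dist):
            gap = interval_gap(row["start"], row["end"], iv.begin, iv.end)
            if gap < max_dist:
                hits.append((iv.data, gap))
        if hits:
            neighbors[gid] = sorted(hits, key=lambda x: (x[1], x[0]))
    return AdjacencyMap(neighbors=neighbors, max_dist=max_dist)


def signature_adjacency_proportion(
    sig_lnc: SignatureSet,
    sig_coding: SignatureSet,
    adjacency: AdjacencyMap,
    same_type: bool = True,
) -> pd.Series:
    """Per cell type: fraction of signature lncRNAs adjacent to a signature
    protein-coding gene (of the same type unless ``same_type=False``).

    Types with no signature lncRNAs are reported as NaN.
    """
    types = sorted(set(sig_lnc.cell_types) | set(sig_coding.cell_types))
    all_coding = {g for t in sig_coding.cell_types for g in sig_coding.genes_for(t)}
    out = {}
    for cell_type in types:
        lncs = sig_lnc.genes_for(cell_type)
        if not lncs:
            out[cell_type] = np.nan
            continue
        coding_set = (
            set(sig_coding.genes_for(cell_type)) if same_type else all_coding
        )
        hit = sum(
            1
            for lnc in lncs
            if any(c in coding_set for c, _ in adjacency.neighbors_of(lnc))
        )
        out[cell_type] = hit / len(lncs)
    return pd.Series(out, name="adjacent_proportion")


@dataclass
class ConservationComparison:
    median_signature: float
    median_background: float
    delta_median: float
    p: float
    n_signature: int
    n_background: int


def conservation_compare(
    scores: Mapping[str, float] | pd.Series,
    signature_ids: Sequence[str],
    background_ids: Sequence[str],
) -> ConservationComparison:
    """One-sided rank-sum test of signature conservation exceeding background.

    The two id sets must be non-empty and disjoint; ids absent from
    ``scores`` raise.
    """
    scores = pd.Series(scores)
    sig = list(signature_ids)
    bg = list(background_ids)
    if not sig or not bg:
        raise ValueError("both gene sets must be non-empty")
    overlap = set(sig) & set(bg)
    if overlap:
        raise ValueError(f"gene sets overlap: {sorted(overlap)[:5]}")
    missing = (set(sig) | set(bg)) - set(scores.index)
    if missing:
        raise ValueError(f"genes without conservation scores: {sorted(missing)[:5]}")
    x = scores.loc[sig].to_numpy(dtype=float)
    y = scores.loc[bg].to_numpy(dtype=float)
    result = rank_sum_test(x, y, alternative="greater")
    return ConservationComparison(
        median_signature=float(np.median(x)),
        median_background=float(np.median(y)),
        delta_median=float(np.median(x) - np.median(y)),
        p=result.p,
        n_signature=len(x),
        n_background=len(y),
    )


def neighbor_signature_overlap(
    adjacency: AdjacencyMap,
    sig_lnc: SignatureSet,
    reference_signatures: Sequence[str],
    universe_size: int,
) -> tuple[int, float]:
    """Overlap of {coding neighbors of signature lncRNAs} with a reference
    gene set, with an upper-tail hypergeometric p-value.

    ``universe_size`` is the number of genes the neighbor set was drawn
    from (e.g. all expressed protein-coding genes); it must be at least as
    large as both sets.
    """
    sig_lnc_ids = {g for t in sig_lnc.cell_types for g in sig_lnc.genes_for(t)}
    neighbor_set = adjacency.coding_neighbors(sorted(sig_lnc_ids))
    reference = set(reference_signatures)
    overlap = len(neighbor_set & reference)
    p = hypergeometric_overlap_test(
        overlap, len(neighbor_set), len(reference), universe_size
    )
    return overlap, p
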