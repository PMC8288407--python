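"""Cell-type signature genes and pairwise differential-expression structure.

Signature calling is one-vs-rest: each gene is tested per cell type with the
Wilcoxon rank-sum test on log2(TPM/10+1) values, p-values are BH-adjusted
within each type, and a gene is a signature of the type when q <= max_q,
log2 fold change >= min_lfc and it is detected in at least ``min_pct_in`` of
the type's cells. Fold changes are computed on de-logged means
(2**x - 1, i.e. TPM/10) with a small pseudocount, which is stable for
sparse data.

Pairwise DEG counts between all type pairs give a square, symmetric,
zero-diagonal matrix; its scaled variant (divided by the matrix maximum)
is the quantity compared between the coding and lncRNA views, whose
agreement is summarized by a Spearman correlation over off-diagonal
entries.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, rank_sum_matrix, rank_sum_one_vs_rest

_PSEUDOCOUNT = 1e-9
_MIN_CELLS_PER_TYPE = 3

SIGNATURE_COLUMNS = ["cell_type", "gene_id", "log2fc", "p", "q", "pct_in", "pct_out"]


@dataclass
class SignatureSet:
    """Per-cell-type signature genes with their test statistics.

    ``table`` has one row per (cell_type, gene) signature call, sorted
    within each type by q then descending log2 fold change.
    """

    table: pd.DataFrame
    thresholds: dict

    def __post_init__(self) -> None:
        missing = set(SIGNATURE_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"signature table missing columns: {sorted(missing)}")

    def genes_for(self, cell_type: str) -> list[str]:
        sub = self.table[self.table["cell_type"] == cell_type]
        return sub["gene_id"].tolist()

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.table["cell_type"], self.table["gene_id"]))

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.table["cell_type"].unique())

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, thresholds: dict | None = None) -> "SignatureSet":
        return cls(pd.read_csv(path, sep="\t"), thresholds or {})


def _group_masks(labels: pd.Series) -> dict[str, np.ndarray]:
    values = labels.to_numpy()
    return {t: values == t for t in pd.unique(values)}


def _fold_change_stats(
    expr: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """log2FC on de-logged means, plus detection fractions, per gene."""
    linear = np.exp2(expr) - 1.0
    m_in = linear[mask].mean(axis=0)
    m_out = linear[~mask].mean(axis=0)
    lfc = np.log2((m_in + _PSEUDOCOUNT) / (m_out + _PSEUDOCOUNT))
    pct_in = (expr[mask] > 0).mean(axis=0)
    pct_out = (expr[~mask] > 0).mean(axis=0)
    return lfc, pct_in, pct_out


def find_signatures(
    norm: ad.AnnData,
    groupby: str = "cell_type",
    min_lfc: float = 1.0,
    max_q: float = 0.05,
    min_pct_in: float = 0.25,
    top_n: int | None = None,
) -> SignatureSet:
    """Call signature genes for every cell type, one-vs-rest.

    Parameters
    ----------
    norm
        log2(TPM/10+1) matrix with a ``groupby`` column in ``.obs``.
    min_lfc, max_q, min_pct_in
        Thresholds a gene must pass to be a signature of a type.
    top_n
        If given, ignore the thresholds and instead report the top-N genes
        per type ranked by (q, -log2FC), restricted to positive fold change.

    Types with fewer than 3 cells are skipped with a warning.
    """
    if groupby not in norm.obs:
        raise ValueError(f"norm.obs lacks column {groupby!r}")
    expr = np.asarray(norm.X, dtype=float)
    masks = _group_masks(norm.obs[groupby])
    if len(masks) < 2:
        raise ValueError("need at least two cell types")

    frames: list[pd.DataFrame] = []
    genes = norm.var_names.to_numpy()
    eligible = {
        t: m for t, m in masks.items() if int(m.sum()) >= _MIN_CELLS_PER_TYPE
    }
    for cell_type in set(masks) - set(eligible):
        warnings.warn(
            f"skipping {cell_type}: only {int(masks[cell_type].sum())} cells "
            f"(< {_MIN_CELLS_PER_TYPE})"
        )
    if len(eligible) < 2:
        raise ValueError("need at least two cell types with >= 3 cells")
    tests = rank_sum_one_vs_rest(
        expr, norm.obs[groupby].to_numpy(), alternative="two-sided"
    )
    for cell_type, mask in eligible.items():
        _, p = tests[cell_type]
        q = bh_adjust(np.clip(p, 1e-300, 1.0))
        lfc, pct_in, pct_out = _fold_change_stats(expr, mask)
        frame = pd.DataFrame(
            {
                "cell_type": cell_type,
                "gene_id": genes,
                "log2fc": lfc,
                "p": p,
                "q": q,
                "pct_in": pct_in,
                "pct_out": pct_out,
            }
        )
        if top_n is not None:
            frame = frame[frame["log2fc"] > 0]
            frame = frame.sort_values(["q", "log2fc"], ascending=[True, False])
            frame = frame.head(top_n)
        else:
            keep = (
                (frame["q"] <= max_q)
                & (frame["log2fc"] >= min_lfc)
                & (frame["pct_in"] >= min_pct_in)
            )
            frame = frame[keep]
            frame = frame.sort_values(["q", "log2fc"], ascending=[True, False])
        frames.append(frame)
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=SIGNATURE_COLUMNS)
    )
    return SignatureSet(
        table=table,
        thresholds={
            "min_lfc": min_lfc,
            "max_q": max_q,
            "min_pct_in": min_pct_in,
            "top_n": top_n,
        },
    )


@dataclass
class DEGCountMatrix:
    """Numbers of differentially expressed genes between all type pairs."""

    counts: pd.DataFrame  # square, symmetric, zero diagonal

    def __post_init__(self) -> None:
        c = self.counts
        if not c.index.equals(c.columns):
            raise ValueError("DEG matrix must be square with matching labels")
        if not np.array_equal(c.values, c.values.T):
            raise ValueError("DEG matrix must be symmetric")
        if np.any(np.diag(c.values) != 0):
            raise ValueError("DEG matrix must have a zero diagonal")

    @property
    def scaled(self) -> pd.DataFrame:
        """Counts divided by the matrix maximum (in [0, 1])."""
        peak = self.counts.values.max()
        return self.counts / peak if peak > 0 else self.counts.astype(float)

    @property
    def scaled_minmax(self) -> pd.DataFrame:
        """Min-max scaling over off-diagonal entries (alternative view)."""
        vals = self.counts.values
        off = vals[~np.eye(len(vals), dtype=bool)]
        lo, hi = off.min(), off.max()
        if hi == lo:
            return self.counts.astype(float) * 0.0
        out = (vals - lo) / (hi - lo)
        np.fill_diagonal(out, 0.0)
        return pd.DataFrame(out, index=self.counts.index, columns=self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")


def pairwise_deg_counts(
    norm: ad.AnnData,
    groupby: str = "cell_type",
    min_lfc: float = 1.0,
    max_q: float = 0.05,
    cell_types: Iterable[str] | None = None,
) -> DEGCountMatrix:
    """Count DEGs between every pair of cell types.

    A gene is a DEG for a pair when q <= max_q and \\|log2FC\\| >= min_lfc in
    the two-group rank-sum comparison. The result is symmetric with a zero
    diagonal by construction.
    """
    if groupby not in norm.obs:
        raise ValueError(f"norm.obs lacks column {groupby!r}")
    expr = np.asarray(norm.X, dtype=float)
    labels = norm.obs[groupby].to_numpy()
    types = list(cell_types) if cell_types is not None else sorted(pd.unique(labels))
    linear = np.exp2(expr) - 1.0

    n = len(types)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        rows_i = labels == types[i]
        if rows_i.sum() < _MIN_CELLS_PER_TYPE:
            warnings.warn(f"skipping pairs with {types[i]}: fewer than 3 cells")
            continue
        for j in range(i + 1, n):
            rows_j = labels == types[j]
            if rows_j.sum() < _MIN_CELLS_PER_TYPE:
                continue
            sel = rows_i | rows_j
            sub = expr[sel]
            mask = rows_i[sel]
            _, p = rank_sum_matrix(sub, mask, alternative="two-sided")
            q = bh_adjust(np.clip(p, 1e-300, 1.0))
            m_a = linear[rows_i].mean(axis=0)
            m_b = linear[rows_j].mean(axis=0)
            lfc = np.log2((m_a + _PSEUDOCOUNT) / (m_b + _PSEUDOCOUNT))
            deg = int(np.count_nonzero((q <= max_q) & (np.abs(lfc) >= min_lfc)))
            counts[i, j] = counts[j, i] = deg
    return DEGCountMatrix(pd.DataFrame(counts, index=types, columns=types))


def deg_concordance(
    coding: DEGCountMatrix, lncrna: DEGCountMatrix
) -> tuple[float, pd.DataFrame]:
    """Agreement between the coding and lncRNA DEG structures.

    Returns the Spearman correlation over off-diagonal entries and a
    composite scaled matrix with the coding counts in the lower triangle
    and the lncRNA counts in the upper triangle (for heat-map display).
    """
    if not coding.counts.index.equals(lncrna.counts.index):
        raise ValueError("DEG matrices must share the same cell-type ordering")
    n = len(coding.counts)
    iu = np.triu_indices(n, k=1)
    rho = sps.spearmanr(coding.counts.values[iu], lncrna.counts.values[iu]).statistic
    composite = np.tril(coding.scaled.values) + np.triu(lncrna.scaled.values, k=1)
    np.fill_diagonal(composite, 0.0)
    return float(rho), pd.DataFrame(
        composite, index=coding.counts.index, columns=coding.counts.columns
    )
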