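"""UMI quantification, cell quality filtering and normalization.

Counts are the number of *distinct* UMIs observed per (cell, gene).
Low-quality cells are discarded by lineage-family-specific mapping-rate
thresholds (below 10% for HSPCs and monocytes, 5% for B/NK/neutrophil/
erythroid cells, 2.5% for T cells) and by per-biotype detection cut-offs
(strictly more than ``min_coding`` protein-coding genes, strictly more than
``min_lnc`` lncRNAs). The coding-retained and lncRNA-retained cell sets are
tracked separately, since the two matrices are analysed separately.

Expression is normalized to log2(TPM/10 + 1), with TPM computed per cell
within the biotype being normalized.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

CELL_OBS_COLUMNS = ("donor", "cell_type", "tissue", "mapping_rate")

#: The 32 immunophenotypic cell-type labels, grouped into 7 lineage families.
DEFAULT_CELL_TYPES: dict[str, tuple[str, ...]] = {
    "HSPC": ("HSC", "MPP", "MLP", "CLP", "CMP", "GMP", "MEP"),
    "B": ("ProB", "PreB", "ImmatureB", "NaiveB", "MemoryB", "RegulatoryB", "PlasmaB"),
    "NK": ("NKP", "CytotoxicNK", "CytokineNK"),
    "T": (
        "CD4NaiveT",
        "CD4MemoryT",
        "CD4EffectorT",
        "CD8NaiveT",
        "CD8MemoryT",
        "CD8EffectorT",
    ),
    "monocyte": ("cMoP", "ClassicalMono", "NonclassicalMono"),
    "neutrophil": ("NeuP", "ImmatureNeu", "MatureNeu"),
    "erythrocyte": ("EarlyEry", "IntermediateEry", "LateEry"),
}

#: Mapping-rate retention thresholds per lineage family: a cell is discarded
#: when its mapping rate is strictly below its family's threshold.
DEFAULT_MAPPING_RATE_THRESHOLDS: dict[str, float] = {
    "HSPC": 0.10,
    "monocyte": 0.10,
    "B": 0.05,
    "NK": 0.05,
    "neutrophil": 0.05,
    "erythrocyte": 0.05,
    "T": 0.025,
}


def lineage_family_map(
    cell_types: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, str]:
    """Flatten a family -> labels mapping into label -> family."""
    cell_types = cell_types or DEFAULT_CELL_TYPES
    out: dict[str, str] = {}
    for family, labels in cell_types.items():
        for label in labels:
            out[label] = family
    return out


def count_umis(
    reads: pd.DataFrame,
    cell_ids: Sequence[str] | None = None,
    gene_ids: Sequence[str] | None = None,
    strict: bool = True,
) -> ad.AnnData:
    """Collapse a UMI-level read table into a distinct-UMI count matrix.

    Parameters
    ----------
    reads
        DataFrame with columns ``cell_id, gene_id, umi``; one row per read.
        PCR duplicates (identical UMI for the same cell and gene) collapse
        to a single molecule.
    cell_ids, gene_ids
        Optional full axis orderings; cells/genes without reads then appear
        as all-zero rows/columns. Defaults to sorted observed ids.
    strict
        If True, malformed rows (null or empty fields) raise; otherwise they
        are dropped with their row indices reported via a warning.

    Returns
    -------
    anndata.AnnData
        Integer matrix of distinct-UMI counts, cells x genes.
    """
    required = ["cell_id", "gene_id", "umi"]
    missing = [c for c in required if c not in reads.columns]
    if missing:
        raise ValueError(f"read table missing columns: {missing}")
    table = reads[required]
    bad = (
        table.isna().any(axis=1)
        | (table["umi"].astype(str).str.len() == 0)
        | (table["cell_id"].astype(str).str.len() == 0)
        | (table["gene_id"].astype(str).str.len() == 0)
    )
    if bad.any():
        idx = np.flatnonzero(bad.to_numpy()).tolist()
        if strict:
            raise ValueError(f"malformed read rows at indices {idx[:10]}")
        import warnings

        warnings.warn(f"dropping {len(idx)} malformed read rows: {idx[:10]}")
        table = table[~bad]

    cell_codes, cell_index = pd.factorize(table["cell_id"], sort=False)
    gene_codes, gene_index = pd.factorize(table["gene_id"], sort=False)
    umi_codes, umi_index = pd.factorize(table["umi"], sort=False)

    if cell_ids is None:
        cell_ids = sorted(map(str, cell_index))
    if gene_ids is None:
        gene_ids = sorted(map(str, gene_index))
    matrix = np.zeros((len(cell_ids), len(gene_ids)), dtype=np.int64)

    if len(table):
        n_genes, n_umis = len(gene_index), len(umi_index)
        pair_code = cell_codes.astype(np.int64) * n_genes + gene_codes
        full_code = pair_code * n_umis + umi_codes
        distinct_pairs = np.unique(full_code) // n_umis  # one entry per molecule
        pairs, counts = np.unique(distinct_pairs, return_counts=True)

        cell_pos = pd.Index(cell_ids).get_indexer(cell_index)
        gene_pos = pd.Index(gene_ids).get_indexer(gene_index)
        if (cell_pos < 0).any():
            raise ValueError("read table contains cell ids absent from cell_ids")
        if (gene_pos < 0).any():
            raise ValueError("read table contains gene ids absent from gene_ids")
        matrix[cell_pos[pairs // n_genes], gene_pos[pairs % n_genes]] = counts
    return ad.AnnData(
        X=matrix,
        obs=pd.DataFrame(index=pd.Index(cell_ids, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
    )


def detected_genes(counts: ad.AnnData, biotype: str | None = None) -> pd.Series:
    """Number of genes with count > 0 per cell, optionally within a biotype."""
    X = counts.X
    if biotype is not None:
        if "biotype" not in counts.var:
            raise ValueError("counts.var lacks a 'biotype' column")
        X = X[:, (counts.var["biotype"] == biotype).to_numpy()]
    return pd.Series(np.count_nonzero(X > 0, axis=1), index=counts.obs_names)


@dataclass
class QCReport:
    """Per-rule record of the cell-retention filters."""

    mapping_rate_thresholds: dict[str, float]
    min_coding: int
    min_lnc: int
    n_input: int
    removed_mapping_rate: list[str] = field(default_factory=list)
    removed_low_coding: list[str] = field(default_factory=list)
    removed_low_lnc: list[str] = field(default_factory=list)
    retained_coding: list[str] = field(default_factory=list)
    retained_lncrna: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_mapping_rate": len(self.removed_mapping_rate),
            "n_removed_low_coding": len(self.removed_low_coding),
            "n_removed_low_lnc": len(self.removed_low_lnc),
            "n_retained_coding": len(self.retained_coding),
            "n_retained_lncrna": len(self.retained_lncrna),
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "thresholds": {
                "mapping_rate": self.mapping_rate_thresholds,
                "min_coding": self.min_coding,
                "min_lnc": self.min_lnc,
            },
            **self.summary(),
            "removed_mapping_rate": sorted(self.removed_mapping_rate),
            "removed_low_coding": sorted(self.removed_low_coding),
            "removed_low_lnc": sorted(self.removed_low_lnc),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [("mapping_rate", c) for c in self.removed_mapping_rate]
            + [("low_coding_detection", c) for c in self.removed_low_coding]
            + [("low_lncrna_detection", c) for c in self.removed_low_lnc]
        )
        return pd.DataFrame(rows, columns=["rule", "cell_id"])


@dataclass
class QCResult:
    coding: ad.AnnData
    lncrna: ad.AnnData
    report: QCReport


def qc_filter(
    counts: ad.AnnData,
    min_coding: int = 1000,
    min_lnc: int = 500,
    mapping_rate_thresholds: Mapping[str, float] | None = None,
    families: Mapping[str, str] | None = None,
) -> QCResult:
    """Apply the cell-retention filters and split the matrix by biotype.

    A cell is retained in the coding matrix iff its mapping rate is at or
    above its lineage family's threshold AND strictly more than
    ``min_coding`` protein-coding genes are detected; analogously for the
    lncRNA matrix with ``min_lnc``. The two retained sets generally differ.

    ``counts.obs`` must provide ``cell_type`` and ``mapping_rate``;
    ``counts.var`` must provide ``biotype``.
    """
    thresholds = dict(mapping_rate_thresholds or DEFAULT_MAPPING_RATE_THRESHOLDS)
    families = dict(families or lineage_family_map())
    for col in ("cell_type", "mapping_rate"):
        if col not in counts.obs:
            raise ValueError(f"counts.obs lacks required column {col!r}")
    if "biotype" not in counts.var:
        raise ValueError("counts.var lacks a 'biotype' column")

    unknown = set(counts.obs["cell_type"]) - set(families)
    if unknown:
        raise ValueError(
            f"cell types without a lineage family: {sorted(unknown)[:5]}"
        )
    fam = counts.obs["cell_type"].map(families)
    missing_thr = set(fam) - set(thresholds)
    if missing_thr:
        raise ValueError(f"families without mapping-rate threshold: {missing_thr}")
    thr = fam.map(thresholds).to_numpy(dtype=float)
    rate = counts.obs["mapping_rate"].to_numpy(dtype=float)
    if np.any((rate < 0) | (rate > 1)):
        raise ValueError("mapping rates must lie in [0, 1]")
    mapping_ok = rate >= thr  # "under X%" are discarded, i.e. strictly below

    det_coding = detected_genes(counts, "coding").to_numpy()
    det_lnc = detected_genes(counts, "lncRNA").to_numpy()
    keep_coding = mapping_ok & (det_coding > min_coding)
    keep_lnc = mapping_ok & (det_lnc > min_lnc)

    obs_names = counts.obs_names.to_numpy()
    report = QCReport(
        mapping_rate_thresholds=thresholds,
        min_coding=min_coding,
        min_lnc=min_lnc,
        n_input=counts.n_obs,
        removed_mapping_rate=list(obs_names[~mapping_ok]),
        removed_low_coding=list(obs_names[mapping_ok & (det_coding <= min_coding)]),
        removed_low_lnc=list(obs_names[mapping_ok & (det_lnc <= min_lnc)]),
        retained_coding=list(obs_names[keep_coding]),
        retained_lncrna=list(obs_names[keep_lnc]),
    )
    coding = counts[keep_coding, (counts.var["biotype"] == "coding").to_numpy()].copy()
    lncrna = counts[keep_lnc, (counts.var["biotype"] == "lncRNA").to_numpy()].copy()
    return QCResult(coding=coding, lncrna=lncrna, report=report)


def normalize_log2tpm10(counts: ad.AnnData) -> ad.AnnData:
    """Normalize distinct-UMI counts to log2(TPM/10 + 1).

    TPM is computed per cell over the genes present in the matrix (so when a
    biotype submatrix is normalized, TPM sums to 1e6 within that biotype).
    Zero counts map to exactly 0. A cell with zero total count is a fatal
    error: such cells must be removed by :func:`qc_filter` first.
    """
    X = np.asarray(counts.X, dtype=float)
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        bad = counts.obs_names[totals <= 0][0]
        raise ValueError(f"cell {bad} has zero total count; run qc_filter first")
    tpm = X / totals[:, None] * 1e6
    norm = counts.copy()
    norm.X = np.log2(tpm / 10.0 + 1.0)
    return norm


def detection_stats(
    counts: ad.AnnData, groupby: str = "cell_type"
) -> pd.DataFrame:
    """Per-cell-type distribution of detected gene numbers.

    Returns one row per group with n, mean, median and quartiles of the
    number of genes detected (count > 0) per cell.
    """
    if counts.n_obs == 0:
        raise ValueError("empty count matrix")
    if groupby not in counts.obs:
        raise ValueError(f"counts.obs lacks column {groupby!r}")
    det = detected_genes(counts)
    grouped = det.groupby(counts.obs[groupby], observed=True)
    out = grouped.agg(
        n="size",
        mean="mean",
        median="median",
        q25=lambda s: s.quantile(0.25),
        q75=lambda s: s.quantile(0.75),
    )
    out.index.name = groupby
    return out.sort_values("mean", ascending=False)
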