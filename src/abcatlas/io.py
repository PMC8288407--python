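"""Readers and writers for the on-disk atlas bundle.

Counts travel as MatrixMarket (MTX) with TSV sidecars for genes and cells,
annotation as BED6 plus a biotype column, conservation as a two-column TSV,
regulons as a GMT-like file and the ground-truth record as JSON.
"""
from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio, sparse

from .annotation import GeneModelSet
from .quantify import CELL_OBS_COLUMNS

COUNTS_MTX = "matrix.mtx"
GENES_TSV = "genes.tsv"
CELLS_TSV = "cells.tsv"
ANNOTATION_BED = "annotation.bed"
CONSERVATION_TSV = "conservation.tsv"
REGULONS_GMT = "regulons.gmt"
TRUTH_JSON = "truth.json"


def write_counts(counts: ad.AnnData, outdir: str | Path) -> None:
    """Write a count matrix as MTX plus gene/cell TSV sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sparse.csr_matrix(np.asarray(counts.X))
    spio.mmwrite(outdir / COUNTS_MTX, X, field="integer")
    counts.var.to_csv(outdir / GENES_TSV, sep="\t")
    counts.obs.to_csv(outdir / CELLS_TSV, sep="\t")


def read_counts(indir: str | Path) -> ad.AnnData:
    """Read a count matrix written by :func:`write_counts`."""
    indir = Path(indir)
    X = spio.mmread(indir / COUNTS_MTX).toarray().astype(np.int64)
    var = pd.read_csv(indir / GENES_TSV, sep="\t", index_col=0)
    obs = pd.read_csv(indir / CELLS_TSV, sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    if X.shape != (len(obs), len(var)):
        raise ValueError(
            f"matrix shape {X.shape} does not match sidecars "
            f"({len(obs)} cells, {len(var)} genes)"
        )
    return ad.AnnData(X=X, obs=obs, var=var)


def write_conservation(scores: pd.Series, path: str | Path) -> None:
    frame = scores.rename("conservation").rename_axis("gene_id").reset_index()
    frame.to_csv(path, sep="\t", index=False)


def read_conservation(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t")
    return frame.set_index("gene_id")["conservation"]


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-cell metadata (donor, cell_type, tissue, mapping_rate)."""
    cells = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CELL_OBS_COLUMNS) - set(cells.columns)
    if missing:
        raise ValueError(f"cell metadata missing columns: {sorted(missing)}")
    return cells


def write_atlas_bundle(atlas, outdir: str | Path) -> Path:
    """Write every component of a synthetic atlas to a directory."""
    from .regulons import write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(atlas.counts, outdir)
    atlas.annotation.to_bed(outdir / ANNOTATION_BED)
    write_conservation(atlas.conservation, outdir / CONSERVATION_TSV)
    write_gmt(atlas.regulons, outdir / REGULONS_GMT)
    atlas.truth.to_json(outdir / TRUTH_JSON)
    (outdir / "canonical_tfs.txt").write_text(
        "\n".join(sorted(atlas.canonical_tfs)) + "\n"
    )
    return outdir


def read_annotation(path: str | Path) -> GeneModelSet:
    return GeneModelSet.from_bed(path)
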