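"""Gene models: genomic intervals with biotype.

Coordinates are 0-based half-open throughout (``start`` inclusive, ``end``
exclusive), so the gap between two non-overlapping intervals is
``max(start_a, start_b) - min(end_a, end_b)`` with no off-by-one anywhere.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

BIOTYPES = ("coding", "lncRNA")
STRANDS = ("+", "-")

_BED_COLUMNS = ["chrom", "start", "end", "gene_id", "score", "strand", "biotype"]


@dataclass(frozen=True)
class GeneModel:
    """A single gene: interval plus biotype.

    ``start``/``end`` follow BED conventions (0-based, half-open).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.gene_id}: unknown biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class GeneModelSet:
    """An ordered collection of :class:`GeneModel` with unique ids.

    Backed by a :class:`pandas.DataFrame` indexed by ``gene_id`` with columns
    ``chrom, start, end, strand, biotype``.
    """

    def __init__(self, genes: Iterable[GeneModel] | pd.DataFrame):
        if isinstance(genes, pd.DataFrame):
            df = genes.copy()
            required = {"chrom", "start", "end", "strand", "biotype"}
            missing = required - set(df.columns)
            if missing:
                raise ValueError(f"annotation frame missing columns: {sorted(missing)}")
        else:
            records = list(genes)
            df = pd.DataFrame(
                {
                    "chrom": [g.chrom for g in records],
                    "start": [g.start for g in records],
                    "end": [g.end for g in records],
                    "strand": [g.strand for g in records],
                    "biotype": [g.biotype for g in records],
                },
                index=pd.Index([g.gene_id for g in records], name="gene_id"),
            )
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if len(df):
            if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
                bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])][0]
                raise ValueError(f"invalid interval for gene {bad}")
            if not df["biotype"].isin(BIOTYPES).all():
                raise ValueError("unknown biotype in annotation")
            if not df["strand"].isin(STRANDS).all():
                raise ValueError("invalid strand in annotation")
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        self._df = df

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._df.index

    def __getitem__(self, gene_id: str) -> GeneModel:
        row = self._df.loc[gene_id]
        return GeneModel(
            gene_id=gene_id,
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"],
            biotype=row["biotype"],
        )

    def __iter__(self) -> Iterator[GeneModel]:
        for gene_id in self._df.index:
            yield self[gene_id]

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def gene_ids(self) -> pd.Index:
        return self._df.index

    def subset(self, biotype: str) -> "GeneModelSet":
        if biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {biotype!r}")
        return GeneModelSet(self._df[self._df["biotype"] == biotype])

    def ids_of_biotype(self, biotype: str) -> list[str]:
        return self.subset(biotype).gene_ids.tolist()

    # -- I/O: BED6 + biotype in a 7th column --------------------------------
    def to_bed(self, path: str | Path) -> None:
        out = self._df.reset_index()
        out["score"] = 0
        out[_BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneModelSet":
        df = pd.read_csv(path, sep="\t", header=None, names=_BED_COLUMNS)
        df = df.set_index("gene_id").drop(columns=["score"])
        return cls(df)
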