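"""Regulon activity: rank-recovery scoring, binarization and cluster states.

A regulon is a transcription factor together with its target gene set
(supplied as input; network inference is upstream of this package). The
regulon activity score (RAS) of a cell is the area under the target
recovery curve within the top ``top_fraction`` of the cell's expression
ranking — high when the regulon's targets crowd the top of the ranking,
near the top-fraction baseline for an unrelated gene set. Scores are
binarized per regulon by a deterministic one-dimensional two-means split,
and cluster-level on/off states summarize the binary calls per supplied
cell partition.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

MIN_TARGETS = 5


@dataclass(frozen=True)
class Regulon:
    """A transcription factor and its target set (TF included)."""

    tf: str
    targets: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.tf:
            raise ValueError("regulon TF id must be non-empty")
        object.__setattr__(self, "targets", frozenset(self.targets) | {self.tf})

    @property
    def name(self) -> str:
        return self.tf

    def __len__(self) -> int:
        return len(self.targets)


def read_gmt(path: str | Path) -> list[Regulon]:
    """Read regulons from a GMT-like file: TF, tab, target, target, ..."""
    regulons = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{line_no}: regulon line needs TF and targets")
        regulons.append(Regulon(tf=fields[0], targets=frozenset(fields[1:])))
    return regulons


def write_gmt(regulons: Iterable[Regulon], path: str | Path) -> None:
    lines = [
        "\t".join([r.tf] + sorted(r.targets - {r.tf}))
        for r in regulons
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def ras_auc(
    norm: ad.AnnData, regulon: Regulon, top_fraction: float = 0.05
) -> pd.Series:
    """Regulon activity score for every cell (column of the RAS matrix)."""
    matrix = ras_matrix(norm, [regulon], top_fraction=top_fraction, min_targets=1)
    return matrix[regulon.name]


def ras_matrix(
    norm: ad.AnnData,
    regulons: Sequence[Regulon],
    top_fraction: float = 0.05,
    min_targets: int = MIN_TARGETS,
) -> pd.DataFrame:
    """Cells x regulons matrix of rank-recovery AUC scores in [0, 1].

    Per cell, genes are ranked by descending expression with ties broken by
    the fixed gene order of the matrix. With X = floor(top_fraction *
    n_genes), the recovery curve is r(k) = |targets among top k|/|targets|
    for k = 1..X and RAS = mean_k r(k). Scores are invariant to any
    monotone transform of a cell's expression values.

    Regulons with fewer than ``min_targets`` targets resolvable against the
    matrix are dropped with a warning; a regulon with no resolvable targets
    is an error.
    """
    if not (0.0 < top_fraction < 1.0):
        raise ValueError("top_fraction must lie in (0, 1)")
    if not regulons:
        raise ValueError("no regulons supplied")
    expr = np.asarray(norm.X, dtype=float)
    n_cells, n_genes = expr.shape
    top_x = int(np.floor(top_fraction * n_genes))
    if top_x < 1:
        raise ValueError("top_fraction leaves no genes in the ranking window")
    gene_index = pd.Index(norm.var_names)
    # stable argsort of -expr => descending expression, ties by gene order
    order = np.argsort(-expr, axis=1, kind="stable")[:, :top_x]

    columns: dict[str, np.ndarray] = {}
    for regulon in regulons:
        member = gene_index.isin(regulon.targets)
        n_resolved = int(member.sum())
        if n_resolved == 0:
            raise ValueError(f"regulon {regulon.name}: no targets in the matrix")
        if n_resolved < min_targets:
            warnings.warn(
                f"dropping regulon {regulon.name}: {n_resolved} resolvable "
                f"targets (< {min_targets})"
            )
            continue
        hits = member[order]  # cells x top_x
        recovery = np.cumsum(hits, axis=1) / n_resolved
        columns[regulon.name] = recovery.mean(axis=1)
    if not columns:
        raise ValueError("no regulon passed the minimum-target floor")
    return pd.DataFrame(columns, index=norm.obs_names)


def _two_means_threshold(values: np.ndarray, max_iter: int = 100) -> float:
    """Deterministic 1-D two-means split; returns the midpoint of the two
    final centers. Initialized at the 10th and 90th percentiles."""
    values = np.sort(values)  # fixed summation order: cell-order invariant
    lo, hi = np.percentile(values, [10, 90])
    if lo == hi:  # degenerate percentiles (e.g. a single outlier cell)
        lo, hi = values[0], values[-1]
    if lo == hi:
        raise ValueError("constant values cannot be split")
    c0, c1 = float(lo), float(hi)
    for _ in range(max_iter):
        assign = np.abs(values - c0) <= np.abs(values - c1)
        if assign.all() or (~assign).all():
            break
        n0, n1 = float(values[assign].mean()), float(values[~assign].mean())
        if (n0, n1) == (c0, c1):
            break
        c0, c1 = n0, n1
    return (c0 + c1) / 2.0


@dataclass
class BinarizedRAS:
    """On/off calls per cell and regulon, with the thresholds used."""

    binary: pd.DataFrame
    thresholds: pd.Series
    dropped: list[str]


def binarize_ras(ras: pd.DataFrame) -> BinarizedRAS:
    """Binarize each regulon's activity by a two-means threshold.

    A cell is "on" for a regulon when its RAS strictly exceeds the midpoint
    of the two cluster centers. Regulons with constant RAS are dropped with
    a warning. Requires at least 10 cells.
    """
    if len(ras) < 10:
        raise ValueError("binarization needs at least 10 cells")
    binary = {}
    thresholds = {}
    dropped = []
    for name in ras.columns:
        values = ras[name].to_numpy(dtype=float)
        if np.ptp(values) == 0:
            warnings.warn(f"dropping regulon {name}: constant RAS")
            dropped.append(name)
            continue
        thr = _two_means_threshold(values)
        binary[name] = (values > thr).astype(np.int8)
        thresholds[name] = thr
    if not binary:
        raise ValueError("all regulons had constant RAS")
    return BinarizedRAS(
        binary=pd.DataFrame(binary, index=ras.index),
        thresholds=pd.Series(thresholds, name="threshold"),
        dropped=dropped,
    )


@dataclass
class RegulonStates:
    """Cluster-level on/off regulon states.

    ``states`` is clusters x regulons in {0, 1}; ``specific`` lists, per
    cluster, the regulons on there and on in fewer than ``max_other_on``
    other clusters.
    """

    states: pd.DataFrame
    on_fractions: pd.DataFrame
    specific: dict[str, list[str]]
    min_on_fraction: float
    max_other_on: int

    def activated_regulons(self) -> list[str]:
        on_any = self.states.columns[(self.states.values == 1).any(axis=0)]
        return sorted(on_any)

    def to_tsv(self, path: str | Path) -> None:
        self.states.to_csv(path, sep="\t")


def cluster_regulon_states(
    binarized: BinarizedRAS | pd.DataFrame,
    cluster_labels: Sequence[str] | pd.Series,
    min_on_fraction: float = 0.5,
    max_other_on: int = 2,
) -> RegulonStates:
    """Summarize binary per-cell calls into per-cluster on/off states.

    A regulon is "on" in a cluster when at least ``min_on_fraction`` of the
    cluster's cells are on. Cluster labels are supplied (immunophenotypes,
    lineage families or any partition); every cell must be labeled and no
    cluster may be empty.
    """
    binary = binarized.binary if isinstance(binarized, BinarizedRAS) else binarized
    labels = pd.Series(cluster_labels).reset_index(drop=True)
    labels.index = binary.index
    if labels.isna().any():
        raise ValueError("every cell must carry a cluster label")
    if not (0.0 < min_on_fraction <= 1.0):
        raise ValueError("min_on_fraction must lie in (0, 1]")
    counts = labels.value_counts(dropna=False)  # keeps unused categories
    empty = counts.index[counts == 0].tolist()
    if empty:
        raise ValueError(f"empty clusters: {empty}")
    frac = binary.groupby(labels, observed=True).mean()
    states = (frac >= min_on_fraction).astype(np.int8)
    on_counts = states.sum(axis=0)
    specific = {
        str(cluster): sorted(
            name
            for name in states.columns
            if states.loc[cluster, name] == 1
            and on_counts[name] - 1 < max_other_on
        )
        for cluster in states.index
    }
    return RegulonStates(
        states=states,
        on_fractions=frac,
        specific=specific,
        min_on_fraction=min_on_fraction,
        max_other_on=max_other_on,
    )


def flag_novel_regulons(
    states: RegulonStates, canonical_tfs: Iterable[str] | Mapping[str, str]
) -> set[str]:
    """Regulons activated in at least one cluster whose TF is not canonical.

    ``canonical_tfs`` is the reference list of previously reported
    transcription factors (an editable resource file ships with the
    package; see :func:`load_canonical_tfs`).
    """
    canonical = set(canonical_tfs)
    return {
        name for name in states.activated_regulons() if name not in canonical
    }


def load_canonical_tfs(path: str | Path | None = None) -> set[str]:
    """Load the canonical transcription-factor list (one symbol per line).

    Defaults to the hematopoietic TF compilation shipped under
    ``resources/canonical_tfs.txt``.
    """
    if path is None:
        path = Path(__file__).parent / "resources" / "canonical_tfs.txt"
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
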