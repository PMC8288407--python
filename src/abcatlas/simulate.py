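"""Synthetic blood-cell atlas with recorded ground truth.

Generates every input the pipeline consumes — gene annotation with planted
lncRNA/coding adjacency, cell metadata with planted QC failures, UMI-level
reads with planted cell-type signatures, per-gene conservation scores and
regulon gene sets — together with a :class:`SimTruth` record from which each
planted quantity is exactly recoverable.

Count model: negative binomial per gene (gamma-Poisson with shared
dispersion), scaled by a per-cell capture efficiency. Signature genes of a
cell type have their mean multiplied by the planted fold change in cells of
that type. Defaults emulate the study design at desk scale: 32
immunophenotypic cell types from 21 donors across 7 lineage families, two
biotypes with a planted fraction of lncRNAs within 5 kb of coding partners,
and conservation scores elevated for signature lncRNAs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .annotation import GeneModel, GeneModelSet
from .quantify import DEFAULT_CELL_TYPES, DEFAULT_MAPPING_RATE_THRESHOLDS, lineage_family_map

MAX_ADJACENT_GAP = 5000  # strictly-less-than adjacency window, bp
_UNIT_MARGIN = 6000  # spacing between placement units; > MAX_ADJACENT_GAP

#: cell types sorted from peripheral blood rather than bone marrow
PERIPHERAL_TYPES = frozenset(
    {
        "NaiveB",
        "MemoryB",
        "RegulatoryB",
        "CytotoxicNK",
        "CytokineNK",
        "CD4NaiveT",
        "CD4MemoryT",
        "CD4EffectorT",
        "CD8NaiveT",
        "CD8MemoryT",
        "CD8EffectorT",
    }
)


@dataclass(frozen=True)
class CellRecord:
    """Per-cell metadata."""

    cell_id: str
    donor: str
    cell_type: str
    tissue: str
    mapping_rate: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mapping_rate <= 1.0):
            raise ValueError(f"{self.cell_id}: mapping_rate outside [0, 1]")


@dataclass
class SimTruth:
    """Ground-truth record of every planted quantity."""

    signature_plan: dict[str, dict] = field(default_factory=dict)
    coupled_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    coupling_fraction: float = 0.0
    conservation_shift: float = 0.0
    nb_dispersion: float = 0.0
    seed: int = 0
    qc_fail_cells: list[str] = field(default_factory=list)
    regulon_plan: dict[str, dict] = field(default_factory=dict)

    def signature_pairs(
        self, annotation: GeneModelSet | None = None, biotype: str | None = None
    ) -> set[tuple[str, str]]:
        """Planted (cell_type, gene_id) pairs, optionally per biotype."""
        keep = None
        if biotype is not None:
            if annotation is None:
                raise ValueError("annotation required to filter by biotype")
            keep = set(annotation.ids_of_biotype(biotype))
        pairs = set()
        for cell_type, plan in self.signature_plan.items():
            for gene in plan["genes"]:
                if keep is None or gene in keep:
                    pairs.add((cell_type, gene))
        return pairs

    def coupled_lncrnas(self) -> set[str]:
        return {lnc for lnc, _, _ in self.coupled_pairs}

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["coupled_pairs"] = [list(t) for t in self.coupled_pairs]
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        payload["coupled_pairs"] = [
            (a, b, int(g)) for a, b, g in payload.get("coupled_pairs", [])
        ]
        return cls(**payload)


@dataclass
class AtlasConfig:
    """Study-design parameters of the synthetic atlas.

    Defaults are the package's standing desk-scale emulation of the study:
    32 immunophenotypic types x 50 cells from 21 donors, 2000 coding and
    1000 lncRNA genes, 5-fold planted signatures, 60% of lncRNAs coupled to
    a coding partner within 5 kb, and a +0.3 conservation shift for
    signature lncRNAs.
    """

    cell_types: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_CELL_TYPES.items()}
    )
    n_per_type: int = 50
    n_donors: int = 21
    qc_fail_fraction: float = 0.05
    n_coding: int = 2000
    n_lnc: int = 1000
    coupling_fraction: float = 0.6
    genome_length: int = 50_000_000
    fold_change: float = 5.0
    sig_coding_min: int = 10
    sig_coding_max: int = 40
    base_mean_median: float = 1.2
    base_mean_sigma: float = 0.8
    lnc_expression_factor: float = 0.5
    capture_low: float = 0.8
    capture_high: float = 1.2
    nb_dispersion: float = 0.3
    duplicate_rate: float = 0.1
    conservation_background_mean: float = 0.15
    conservation_coding_mean: float = 0.5
    conservation_shift: float = 0.3
    conservation_concentration: float = 8.0
    n_broad_regulons: int = 2
    n_silent_regulons: int = 1
    n_novel_families: int = 3

    @property
    def type_labels(self) -> list[str]:
        return [t for labels in self.cell_types.values() for t in labels]

    @property
    def families(self) -> dict[str, str]:
        return lineage_family_map(self.cell_types)

    @classmethod
    def small(cls, **overrides) -> "AtlasConfig":
        """A reduced design (8 types, 900 genes) for fast exploratory runs."""
        defaults = dict(
            cell_types={
                "HSPC": ("HSC", "MPP"),
                "B": ("NaiveB", "MemoryB"),
                "NK": ("CytotoxicNK",),
                "T": ("CD4NaiveT",),
                "monocyte": ("ClassicalMono",),
                "erythrocyte": ("EarlyEry",),
            },
            n_per_type=30,
            n_donors=6,
            n_coding=600,
            n_lnc=300,
            genome_length=20_000_000,
            n_novel_families=2,
            n_broad_regulons=1,
        )
        defaults.update(overrides)
        return cls(**defaults)


def coding_gene_id(i: int) -> str:
    return f"PCG{i:05d}"


def lnc_gene_id(i: int) -> str:
    return f"LNC{i:05d}"


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------
def gen_annotation(
    n_coding: int,
    n_lnc: int,
    coupling_fraction: float,
    genome_length: int,
    seed: int | np.random.Generator = 0,
    pair_plan: Mapping[str, str] | None = None,
    chrom: str = "chr1",
) -> tuple[GeneModelSet, SimTruth]:
    """Place genes on a synthetic chromosome with planted adjacency.

    Exactly ``round(coupling_fraction * n_lnc)`` lncRNAs are placed with a
    gap strictly below 5 kb to a coding gene; every remaining lncRNA ends up
    at least 5 kb away from every coding gene. ``pair_plan`` (lncRNA id ->
    coding id) forces specific partners; the remaining coupled lncRNAs are
    paired with unused coding genes. At most two lncRNAs may share one
    coding partner.

    Returns the annotation and a :class:`SimTruth` whose ``coupled_pairs``
    records (lncRNA, coding gene, planted gap).
    """
    if n_coding < 1 or n_lnc < 1:
        raise ValueError("n_coding and n_lnc must be >= 1")
    if not (0.0 <= coupling_fraction <= 1.0):
        raise ValueError("coupling_fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, int) else 0

    coding_ids = [coding_gene_id(i) for i in range(n_coding)]
    lnc_ids = [lnc_gene_id(i) for i in range(n_lnc)]
    n_coupled = round(coupling_fraction * n_lnc)
    if n_coupled > 2 * n_coding:
        raise ValueError(
            f"cannot couple {n_coupled} lncRNAs to {n_coding} coding genes "
            "(at most two partners per coding gene)"
        )

    pair_plan = dict(pair_plan or {})
    unknown = set(pair_plan) - set(lnc_ids) | set(pair_plan.values()) - set(coding_ids)
    if unknown:
        raise ValueError(f"pair_plan references unknown genes: {sorted(unknown)[:5]}")
    if len(pair_plan) > n_coupled:
        raise ValueError("pair_plan larger than the requested coupled count")

    partners: dict[str, list[str]] = {c: [] for c in coding_ids}
    for lnc, coding in pair_plan.items():
        partners[coding].append(lnc)
        if len(partners[coding]) > 2:
            raise ValueError(f"more than two lncRNAs forced onto {coding}")
    # fill the remaining coupled quota with unplanned lncRNAs on free coding genes
    free_lnc = [l for l in lnc_ids if l not in pair_plan]
    extra = n_coupled - len(pair_plan)
    extra_lnc = list(rng.choice(free_lnc, size=extra, replace=False)) if extra else []
    free_coding = [c for c in coding_ids if not partners[c]] + [
        c for c in coding_ids if len(partners[c]) == 1
    ]
    for lnc, coding in zip(extra_lnc, free_coding):
        partners[coding].append(lnc)
    coupled = set(pair_plan) | set(extra_lnc)
    lonely = [l for l in lnc_ids if l not in coupled]

    genes: list[GeneModel] = []
    coupled_pairs: list[tuple[str, str, int]] = []

    # one placement unit per coding gene (plus its partners), one per lone lncRNA
    units: list[tuple[str, str]] = [("coding", c) for c in coding_ids] + [
        ("lnc", l) for l in lonely
    ]
    order = rng.permutation(len(units))
    cursor = int(rng.integers(0, 10_000))
    for k in order:
        kind, gid = units[k]
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "lnc":
            length = int(rng.integers(300, 2001))
            genes.append(GeneModel(gid, chrom, cursor, cursor + length, strand, "lncRNA"))
            cursor += length
        else:
            # optionally an upstream partner, the coding gene, then a downstream one
            mates = partners[gid]
            clen = int(rng.integers(1000, 5001))
            if len(mates) == 2:
                up = mates[1]
                ulen = int(rng.integers(300, 2001))
                gap = int(rng.integers(0, MAX_ADJACENT_GAP))
                genes.append(
                    GeneModel(up, chrom, cursor, cursor + ulen,
                              "+" if rng.random() < 0.5 else "-", "lncRNA")
                )
                coupled_pairs.append((up, gid, gap))
                cursor += ulen + gap
            genes.append(GeneModel(gid, chrom, cursor, cursor + clen, strand, "coding"))
            cursor += clen
            if mates:
                down = mates[0]
                dlen = int(rng.integers(300, 2001))
                gap = int(rng.integers(0, MAX_ADJACENT_GAP))
                cursor += gap
                genes.append(
                    GeneModel(down, chrom, cursor, cursor + dlen,
                              "+" if rng.random() < 0.5 else "-", "lncRNA")
                )
                coupled_pairs.append((down, gid, gap))
                cursor += dlen
        cursor += _UNIT_MARGIN + int(rng.integers(0, 2000))
    if cursor > genome_length:
        raise ValueError(
            f"genome_length {genome_length} too small: layout needs {cursor} bp"
        )

    annotation = GeneModelSet(genes)
    truth = SimTruth(
        coupled_pairs=sorted(coupled_pairs),
        coupling_fraction=coupling_fraction,
        seed=seed_val,
    )
    assert len(truth.coupled_lncrnas()) == n_coupled
    return annotation, truth


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------
def gen_cells(
    cell_types: Sequence[str],
    n_per_type: int,
    n_donors: int,
    qc_fail_fraction: float,
    seed: int | np.random.Generator = 0,
    families: Mapping[str, str] | None = None,
    mapping_rate_thresholds: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Generate cell metadata with a planted fraction of QC failures.

    ``round(qc_fail_fraction * n_cells)`` cells receive a mapping rate
    strictly below their lineage family's retention threshold; all others
    land safely above it. Returns the metadata frame (indexed by cell_id,
    with donor/cell_type/tissue/mapping_rate columns) and the list of
    planted failures.
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    if not (0.0 <= qc_fail_fraction < 1.0):
        raise ValueError("qc_fail_fraction must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    families = dict(families or lineage_family_map())
    thresholds = dict(mapping_rate_thresholds or DEFAULT_MAPPING_RATE_THRESHOLDS)
    unknown = set(cell_types) - set(families)
    if unknown:
        raise ValueError(f"cell types without a lineage family: {sorted(unknown)}")

    donors = [f"D{i + 1:02d}" for i in range(n_donors)]
    records: list[dict] = []
    for t_idx, cell_type in enumerate(cell_types):
        for j in range(n_per_type):
            cell_id = f"{cell_type}_c{j + 1:04d}"
            records.append(
                {
                    "cell_id": cell_id,
                    "donor": donors[(t_idx * n_per_type + j) % n_donors],
                    "cell_type": cell_type,
                    "tissue": (
                        "peripheral_blood"
                        if cell_type in PERIPHERAL_TYPES
                        else "bone_marrow"
                    ),
                }
            )
    cells = pd.DataFrame(records).set_index("cell_id")

    n_cells = len(cells)
    n_fail = round(qc_fail_fraction * n_cells)
    fail_idx = rng.choice(n_cells, size=n_fail, replace=False)
    is_fail = np.zeros(n_cells, dtype=bool)
    is_fail[fail_idx] = True
    thr = cells["cell_type"].map(families).map(thresholds).to_numpy(dtype=float)
    pass_rates = thr + (1.0 - thr) * rng.uniform(0.3, 0.95, size=n_cells)
    fail_rates = thr * rng.uniform(0.2, 0.9, size=n_cells)
    cells["mapping_rate"] = np.where(is_fail, fail_rates, pass_rates)
    return cells, sorted(cells.index[is_fail])


# ---------------------------------------------------------------------------
# counts and reads
# ---------------------------------------------------------------------------
def _base_means(annotation: GeneModelSet, config: AtlasConfig, rng) -> pd.Series:
    mu = rng.lognormal(
        mean=np.log(config.base_mean_median),
        sigma=config.base_mean_sigma,
        size=len(annotation),
    )
    mu = pd.Series(mu, index=annotation.gene_ids)
    lnc = annotation.df["biotype"] == "lncRNA"
    mu[lnc] *= config.lnc_expression_factor
    return mu


def gen_counts(
    annotation: GeneModelSet,
    cells: pd.DataFrame,
    truth: SimTruth,
    config: AtlasConfig,
    rng: np.random.Generator,
    base_means: pd.Series | None = None,
) -> ad.AnnData:
    """Draw the distinct-UMI count matrix from the planted NB model."""
    if base_means is None:
        base_means = _base_means(annotation, config, rng)
    mu = base_means.to_numpy(dtype=float)
    gene_pos = pd.Index(annotation.gene_ids)
    capture = rng.uniform(config.capture_low, config.capture_high, size=len(cells))
    mean = capture[:, None] * mu[None, :]

    type_of = cells["cell_type"].to_numpy()
    for cell_type, plan in truth.signature_plan.items():
        rows = np.flatnonzero(type_of == cell_type)
        cols = gene_pos.get_indexer(plan["genes"])
        if (cols < 0).any():
            raise ValueError(f"signature plan for {cell_type} names unknown genes")
        mean[np.ix_(rows, cols)] *= plan["fold_change"]

    alpha = config.nb_dispersion
    if alpha > 0:
        lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    else:
        lam = mean
    counts = rng.poisson(lam).astype(np.int64)
    adata = ad.AnnData(X=counts, obs=cells.copy(), var=annotation.df.copy())
    adata.var["base_mean"] = mu
    return adata


def _encode_umis(index_within_key: np.ndarray, k: int = 8) -> np.ndarray:
    """Deterministic ACGT k-mers, distinct for distinct indices (< 4**k)."""
    if index_within_key.size and index_within_key.max() >= 4**k:
        raise ValueError("per-molecule index exceeds UMI space")
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = np.empty((index_within_key.size, k), dtype=np.uint8)
    v = index_within_key.astype(np.int64)
    for j in range(k - 1, -1, -1):
        out[:, j] = letters[v % 4]
        v //= 4
    return out.view(f"S{k}").ravel().astype(str)


def gen_reads(
    counts: ad.AnnData,
    duplicate_rate: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Expand a count matrix into a UMI-level read table.

    Each molecule becomes one row (cell_id, gene_id, umi) with a distinct
    UMI within its (cell, gene); PCR duplicates are injected by re-emitting
    ``round(duplicate_rate * n_molecules)`` randomly chosen rows, so
    collapsing distinct UMIs recovers the input matrix exactly.
    """
    if duplicate_rate < 0:
        raise ValueError("duplicate_rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(counts.X, dtype=np.int64)
    rows, cols = np.nonzero(X)
    vals = X[rows, cols]
    total = int(vals.sum())
    cell_codes = np.repeat(rows, vals)
    gene_codes = np.repeat(cols, vals)
    # index of each molecule within its (cell, gene) key
    offsets = np.cumsum(vals) - vals
    within = np.arange(total, dtype=np.int64) - np.repeat(offsets, vals)
    umis = _encode_umis(within)

    n_dup = round(duplicate_rate * total)
    if n_dup:
        pick = rng.integers(0, total, size=n_dup)
        cell_codes = np.concatenate([cell_codes, cell_codes[pick]])
        gene_codes = np.concatenate([gene_codes, gene_codes[pick]])
        umis = np.concatenate([umis, umis[pick]])
    perm = rng.permutation(len(umis))
    return pd.DataFrame(
        {
            "cell_id": pd.Categorical.from_codes(
                cell_codes[perm], categories=counts.obs_names
            ),
            "gene_id": pd.Categorical.from_codes(
                gene_codes[perm], categories=counts.var_names
            ),
            "umi": umis[perm],
        }
    )


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------
def gen_conservation(
    annotation: GeneModelSet,
    truth: SimTruth,
    seed: int | np.random.Generator = 0,
    background_mean: float = 0.15,
    coding_mean: float = 0.5,
    concentration: float = 8.0,
) -> pd.Series:
    """Per-gene conservation scores in [0, 1] (Beta-distributed).

    Signature lncRNAs are drawn with their mean elevated by
    ``truth.conservation_shift`` over the lncRNA background; coding genes
    get their own, higher, mean. Scores emulate gene-level aggregation of
    base-wise conservation (e.g. PhastCons averaged over the gene body).
    """
    if truth.conservation_shift < 0:
        raise ValueError("conservation_shift must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def draw(mean: float, size: int) -> np.ndarray:
        mean = float(np.clip(mean, 0.01, 0.99))
        a = mean * concentration
        b = (1.0 - mean) * concentration
        return rng.beta(a, b, size=size)

    df = annotation.df
    scores = pd.Series(0.0, index=annotation.gene_ids)
    is_lnc = (df["biotype"] == "lncRNA").to_numpy()
    sig_lnc_ids = {
        g
        for pairs in truth.signature_plan.values()
        for g in pairs["genes"]
        if g in annotation and annotation[g].biotype == "lncRNA"
    }
    is_sig_lnc = scores.index.isin(sig_lnc_ids)
    n = len(scores)
    coding_mask = ~is_lnc
    bg_mask = is_lnc & ~is_sig_lnc
    sig_mask = is_lnc & is_sig_lnc
    scores[coding_mask] = draw(coding_mean, int(coding_mask.sum()))
    scores[bg_mask] = draw(background_mean, int(bg_mask.sum()))
    scores[sig_mask] = draw(
        background_mean + truth.conservation_shift, int(sig_mask.sum())
    )
    assert len(scores) == n
    return scores


# ---------------------------------------------------------------------------
# regulons
# ---------------------------------------------------------------------------
def gen_regulons(
    annotation: GeneModelSet,
    truth: SimTruth,
    config: AtlasConfig,
    base_means: pd.Series,
    rng: np.random.Generator,
) -> tuple[list, set[str]]:
    """Plant regulon gene sets over the signature structure.

    One lineage regulon per family (targets = the family's planted coding
    signature genes, TF = the first of them), ``n_broad_regulons`` broad
    regulons over the highest-baseline genes (active everywhere), and
    ``n_silent_regulons`` over the lowest-baseline genes (never active).
    ``n_novel_families`` lineage TFs plus all silent TFs are withheld from
    the canonical list, so only the activated non-canonical TFs should be
    flagged novel downstream.
    """
    from .regulons import Regulon

    families = config.families
    family_types: dict[str, list[str]] = {}
    for label, fam in families.items():
        family_types.setdefault(fam, []).append(label)

    sig_genes_all: set[str] = {
        g for plan in truth.signature_plan.values() for g in plan["genes"]
    }
    coding_ids = annotation.ids_of_biotype("coding")
    regulons: list[Regulon] = []
    plan: dict[str, dict] = {}

    fam_names = [f for f in config.cell_types.keys()]
    novel = set(
        rng.choice(fam_names, size=min(config.n_novel_families, len(fam_names)),
                   replace=False)
    )
    for fam in fam_names:
        targets: list[str] = []
        for label in family_types.get(fam, []):
            if label in truth.signature_plan:
                targets.extend(
                    g
                    for g in truth.signature_plan[label]["genes"]
                    if annotation[g].biotype == "coding"
                )
        targets = sorted(set(targets))
        if len(targets) < 5:
            continue
        tf = targets[0]
        regulons.append(Regulon(tf=tf, targets=frozenset(targets)))
        plan[tf] = {
            "tf": tf,
            "family": fam,
            "kind": "lineage",
            "canonical": fam not in novel,
        }

    nonsig_coding = [g for g in coding_ids if g not in sig_genes_all]
    by_mean = sorted(nonsig_coding, key=lambda g: -base_means[g])
    for i in range(config.n_broad_regulons):
        targets = by_mean[i * 30 : (i + 1) * 30]
        if len(targets) < 5:
            break
        tf = targets[0]
        regulons.append(Regulon(tf=tf, targets=frozenset(targets)))
        plan[tf] = {"tf": tf, "family": None, "kind": "broad", "canonical": True}
    low_by_mean = by_mean[::-1]
    for i in range(config.n_silent_regulons):
        targets = low_by_mean[i * 20 : (i + 1) * 20]
        if len(targets) < 5:
            break
        tf = targets[0]
        regulons.append(Regulon(tf=tf, targets=frozenset(targets)))
        plan[tf] = {"tf": tf, "family": None, "kind": "silent", "canonical": False}

    truth.regulon_plan = plan
    canonical = {tf for tf, meta in plan.items() if meta["canonical"]}
    return regulons, canonical


# ---------------------------------------------------------------------------
# full atlas
# ---------------------------------------------------------------------------
@dataclass
class SyntheticAtlas:
    """Bundle of all generated inputs plus their ground truth."""

    counts: ad.AnnData
    annotation: GeneModelSet
    conservation: pd.Series
    regulons: list
    canonical_tfs: set[str]
    truth: SimTruth
    config: AtlasConfig

    def reads(self, seed: int | np.random.Generator = 0) -> pd.DataFrame:
        return gen_reads(self.counts, self.config.duplicate_rate, seed)


def _plan_signatures(
    config: AtlasConfig, rng: np.random.Generator
) -> tuple[dict[str, dict], dict[str, str]]:
    """Assign planted signature genes per type and the forced lnc pairing."""
    labels = config.type_labels
    k_coding = rng.integers(
        config.sig_coding_min, config.sig_coding_max + 1, size=len(labels)
    )
    k_lnc = np.maximum(2, np.round(k_coding / 2).astype(int))
    need_c, need_l = int(k_coding.sum()), int(k_lnc.sum())
    if need_c > config.n_coding or need_l > config.n_lnc:
        raise ValueError("not enough genes to host the signature plan")
    coding_pool = rng.permutation(config.n_coding)[:need_c]
    lnc_pool = rng.permutation(config.n_lnc)[:need_l]

    plan: dict[str, dict] = {}
    pair_plan: dict[str, str] = {}
    ci = li = 0
    for label, kc, kl in zip(labels, k_coding, k_lnc):
        c_genes = [coding_gene_id(i) for i in coding_pool[ci : ci + kc]]
        l_genes = [lnc_gene_id(i) for i in lnc_pool[li : li + kl]]
        ci += kc
        li += kl
        plan[label] = {
            "genes": sorted(c_genes) + sorted(l_genes),
            "fold_change": config.fold_change,
        }
        n_coupled_here = round(config.coupling_fraction * kl)
        for lnc, coding in zip(l_genes[:n_coupled_here], c_genes):
            pair_plan[lnc] = coding
    return plan, pair_plan


def simulate_atlas(config: AtlasConfig | None = None, seed: int = 0) -> SyntheticAtlas:
    """Generate the full synthetic atlas; bit-reproducible for a given seed."""
    config = config or AtlasConfig()
    rng = np.random.default_rng(seed)
    plan, pair_plan = _plan_signatures(config, rng)

    annotation, truth = gen_annotation(
        config.n_coding,
        config.n_lnc,
        config.coupling_fraction,
        config.genome_length,
        rng,
        pair_plan=pair_plan,
    )
    truth.seed = seed
    truth.signature_plan = plan
    truth.nb_dispersion = config.nb_dispersion
    truth.conservation_shift = config.conservation_shift

    cells, qc_fail = gen_cells(
        config.type_labels,
        config.n_per_type,
        config.n_donors,
        config.qc_fail_fraction,
        rng,
        families=config.families,
    )
    truth.qc_fail_cells = qc_fail

    base_means = _base_means(annotation, config, rng)
    counts = gen_counts(annotation, cells, truth, config, rng, base_means=base_means)
    conservation = gen_conservation(
        annotation,
        truth,
        rng,
        background_mean=config.conservation_background_mean,
        coding_mean=config.conservation_coding_mean,
        concentration=config.conservation_concentration,
    )
    regulons, canonical = gen_regulons(annotation, truth, config, base_means, rng)
    return SyntheticAtlas(
        counts=counts,
        annotation=annotation,
        conservation=conservation,
        regulons=regulons,
        canonical_tfs=canonical,
        truth=truth,
        config=config,
    )


def signature_recovery(
    signatures, truth: SimTruth, annotation: GeneModelSet, biotype: str
) -> tuple[float, float]:
    """Precision and recall of called signatures against the planted plan,
    measured over (cell_type, gene) pairs of the given biotype."""
    planted = truth.signature_pairs(annotation, biotype)
    keep = set(annotation.ids_of_biotype(biotype))
    called = {
        (t, g) for t, g in signatures.pairs() if g in keep
    }
    if not called:
        return (float("nan"), 0.0)
    tp = len(called & planted)
    return tp / len(called), tp / len(planted)
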