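"""End-to-end pipeline: one config, fixed seed, a report bundle.

Stages: simulate-or-load inputs, UMI collapsing, QC filtering, per-biotype
normalization, detection statistics, signature calling, pairwise DEG
matrices and coding/lncRNA concordance, lncRNA characterization
(specificity, adjacency, conservation, neighbor overlap), regulon activity
states and novelty flags, and self-projection accuracy. Every stochastic
stage derives from the single configured seed, so identical config + seed
produces a byte-identical summary.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as abcio
from .annotation import GeneModelSet
from .lncrna import (
    adjacency_scan,
    conservation_compare,
    neighbor_signature_overlap,
    signature_adjacency_proportion,
    specificity_scores,
)
from .projection import self_projection_accuracy
from .quantify import (
    DEFAULT_MAPPING_RATE_THRESHOLDS,
    count_umis,
    detection_stats,
    lineage_family_map,
    normalize_log2tpm10,
    qc_filter,
)
from .regulons import (
    binarize_ras,
    cluster_regulon_states,
    flag_novel_regulons,
    load_canonical_tfs,
    ras_matrix,
    read_gmt,
)
from .signatures import deg_concordance, find_signatures, pairwise_deg_counts
from .simulate import AtlasConfig, SyntheticAtlas, signature_recovery, simulate_atlas
from .stats import rank_sum_test

logger = logging.getLogger("abcatlas")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; round-trips through YAML unchanged."""

    seed: int = 0
    outdir: str = "abc_out"
    simulate: dict | None = field(default_factory=dict)
    paths: dict | None = None
    qc: dict = field(
        default_factory=lambda: {
            "min_coding": 1000,
            "min_lnc": 500,
            "mapping_rate_thresholds": dict(DEFAULT_MAPPING_RATE_THRESHOLDS),
        }
    )
    de: dict = field(
        default_factory=lambda: {"min_lfc": 1.0, "max_q": 0.05, "min_pct_in": 0.25}
    )
    adjacency: dict = field(default_factory=lambda: {"max_dist": 5000})
    regulons: dict = field(
        default_factory=lambda: {
            "top_fraction": 0.05,
            "min_on_fraction": 0.5,
            "max_other_on": 2,
        }
    )
    projection: dict = field(
        default_factory=lambda: {"threshold": 0.7, "n_features": 500, "n_folds": 5}
    )

    def __post_init__(self) -> None:
        if self.simulate is None and self.paths is None:
            raise ValueError("config needs either a 'simulate' block or 'paths'")
        checks = [
            (0 < self.de["max_q"] <= 1, "de.max_q must lie in (0, 1]"),
            (0 <= self.de["min_pct_in"] <= 1, "de.min_pct_in must lie in [0, 1]"),
            (self.adjacency["max_dist"] > 0, "adjacency.max_dist must be positive"),
            (
                0 < self.regulons["top_fraction"] < 1,
                "regulons.top_fraction must lie in (0, 1)",
            ),
            (
                0 < self.regulons["min_on_fraction"] <= 1,
                "regulons.min_on_fraction must lie in (0, 1]",
            ),
            (
                0 <= self.projection["threshold"] <= 1,
                "projection.threshold must lie in [0, 1]",
            ),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "outdir": self.outdir,
            "simulate": self.simulate,
            "paths": self.paths,
            "qc": self.qc,
            "de": self.de,
            "adjacency": self.adjacency,
            "regulons": self.regulons,
            "projection": self.projection,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        base = cls()
        for block in ("qc", "de", "adjacency", "regulons", "projection"):
            merged = dict(getattr(base, block))
            merged.update(payload.get(block) or {})
            payload[block] = merged
        return cls(**payload)


def default_synthetic_config(seed: int = 0, outdir: str = "abc_out") -> PipelineConfig:
    """Pipeline config for the default synthetic atlas.

    Detection cut-offs are scaled to the toy gene universe (600 of 2000
    coding genes, 150 of 1000 lncRNAs) so they play the same proportional
    role as the absolute cut-offs do against a full genome annotation.
    """
    config = PipelineConfig(seed=seed, outdir=outdir, simulate={})
    config.qc["min_coding"] = 600
    config.qc["min_lnc"] = 150
    return config


def _simulate_inputs(config: PipelineConfig):
    overrides = dict(config.simulate or {})
    cell_types = overrides.pop("cell_types", None)
    if cell_types is not None:
        overrides["cell_types"] = {k: tuple(v) for k, v in cell_types.items()}
    atlas = simulate_atlas(AtlasConfig(**overrides), seed=config.seed)
    return atlas


def _load_inputs(config: PipelineConfig):
    paths = config.paths or {}
    counts = abcio.read_counts(paths["counts_dir"])
    annotation = GeneModelSet.from_bed(paths["annotation"])
    counts.var = counts.var.join(
        annotation.df, how="left", rsuffix="_annot"
    ) if "biotype" not in counts.var else counts.var
    conservation = abcio.read_conservation(paths["conservation"])
    regulons = read_gmt(paths["regulons"])
    canonical = (
        load_canonical_tfs(paths.get("canonical_tfs"))
        if paths.get("canonical_tfs")
        else load_canonical_tfs()
    )
    return counts, annotation, conservation, regulons, canonical


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the report directory.

    Writes stage outputs (TSV/JSON) and a machine-readable ``summary.json``
    holding retained cell counts per biotype, detection statistics,
    signature counts, DEG concordance, adjacency proportions, conservation
    and specificity contrasts, regulon counts and projection accuracy.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"seed": config.seed}
    rng = np.random.default_rng(config.seed)

    # ---- inputs ----------------------------------------------------------
    atlas: SyntheticAtlas | None = None
    if config.simulate is not None:
        logger.info("stage simulate: generating synthetic atlas")
        atlas = _simulate_inputs(config)
        annotation = atlas.annotation
        conservation = atlas.conservation
        regulons = atlas.regulons
        canonical = atlas.canonical_tfs
        logger.info("stage reads: expanding counts to UMI-level reads")
        reads = atlas.reads(seed=rng)
        counts = count_umis(
            reads,
            cell_ids=list(atlas.counts.obs_names),
            gene_ids=list(atlas.counts.var_names),
        )
        if not np.array_equal(np.asarray(counts.X), np.asarray(atlas.counts.X)):
            raise RuntimeError("UMI collapsing did not recover simulated counts")
        counts.obs = atlas.counts.obs.copy()
        counts.var = atlas.counts.var.copy()
        families = atlas.config.families
    else:
        logger.info("stage load: reading inputs from paths")
        counts, annotation, conservation, regulons, canonical = _load_inputs(config)
        families = lineage_family_map()

    summary["inputs"] = {
        "n_cells": int(counts.n_obs),
        "n_genes": int(counts.n_vars),
        "n_coding": int((counts.var["biotype"] == "coding").sum()),
        "n_lncrna": int((counts.var["biotype"] == "lncRNA").sum()),
        "n_regulons": len(regulons),
    }

    # ---- QC and normalization -------------------------------------------
    logger.info("stage qc: %d cells in", counts.n_obs)
    qc = qc_filter(
        counts,
        min_coding=config.qc["min_coding"],
        min_lnc=config.qc["min_lnc"],
        mapping_rate_thresholds=config.qc["mapping_rate_thresholds"],
        families=families,
    )
    qc.report.to_json(outdir / "qc_report.json")
    qc.report.to_frame().to_csv(outdir / "qc_removed.tsv", sep="\t", index=False)
    summary["qc"] = qc.report.summary()
    logger.info(
        "stage qc: retained %d coding / %d lncRNA cells",
        len(qc.report.retained_coding),
        len(qc.report.retained_lncrna),
    )

    norm_coding = normalize_log2tpm10(qc.coding)
    norm_lnc = normalize_log2tpm10(qc.lncrna)

    det_coding = detection_stats(qc.coding)
    det_lnc = detection_stats(qc.lncrna)
    det_coding.to_csv(outdir / "detection_coding.tsv", sep="\t")
    det_lnc.to_csv(outdir / "detection_lncrna.tsv", sep="\t")
    summary["detection"] = {
        "coding_mean_detected": float(
            (det_coding["mean"] * det_coding["n"]).sum() / det_coding["n"].sum()
        ),
        "lncrna_mean_detected": float(
            (det_lnc["mean"] * det_lnc["n"]).sum() / det_lnc["n"].sum()
        ),
        "top_type_coding": det_coding.index[0],
        "top_type_lncrna": det_lnc.index[0],
    }

    # ---- signatures and DEG structure -----------------------------------
    logger.info("stage signatures")
    de = config.de
    sig_coding = find_signatures(
        norm_coding,
        min_lfc=de["min_lfc"],
        max_q=de["max_q"],
        min_pct_in=de["min_pct_in"],
    )
    sig_lnc = find_signatures(
        norm_lnc, min_lfc=de["min_lfc"], max_q=de["max_q"], min_pct_in=de["min_pct_in"]
    )
    sig_coding.to_tsv(outdir / "signatures_coding.tsv")
    sig_lnc.to_tsv(outdir / "signatures_lncrna.tsv")
    summary["signatures"] = {
        "n_signature_coding": len(sig_coding),
        "n_signature_lncrna": len(sig_lnc),
        "n_types_with_coding": len(sig_coding.cell_types),
        "n_types_with_lncrna": len(sig_lnc.cell_types),
    }

    logger.info("stage deg matrices")
    types = sorted(norm_coding.obs["cell_type"].unique())
    deg_coding = pairwise_deg_counts(
        norm_coding, min_lfc=de["min_lfc"], max_q=de["max_q"], cell_types=types
    )
    deg_lnc = pairwise_deg_counts(
        norm_lnc, min_lfc=de["min_lfc"], max_q=de["max_q"], cell_types=types
    )
    deg_coding.to_tsv(outdir / "deg_counts_coding.tsv")
    deg_lnc.to_tsv(outdir / "deg_counts_lncrna.tsv")
    rho, composite = deg_concordance(deg_coding, deg_lnc)
    composite.to_csv(outdir / "deg_composite_scaled.tsv", sep="\t")
    summary["deg"] = {"spearman_rho": rho}

    # ---- lncRNA characterization ----------------------------------------
    logger.info("stage lncrna characterization")
    adjacency = adjacency_scan(annotation, max_dist=config.adjacency["max_dist"])
    adjacency.to_tsv(outdir / "adjacency.tsv")
    proportions = signature_adjacency_proportion(sig_lnc, sig_coding, adjacency)
    proportions.to_csv(outdir / "signature_adjacency.tsv", sep="\t")
    sig_lnc_ids = sorted({g for t in sig_lnc.cell_types for g in sig_lnc.genes_for(t)})
    n_sig_lnc_total = sum(len(sig_lnc.genes_for(t)) for t in sig_lnc.cell_types)
    n_adj = sum(
        1
        for t in sig_lnc.cell_types
        for g in sig_lnc.genes_for(t)
        if any(
            c in set(sig_coding.genes_for(t)) for c, _ in adjacency.neighbors_of(g)
        )
    )
    expressed_lnc = norm_lnc.var_names[(np.asarray(norm_lnc.X) > 0).any(axis=0)]
    background_lnc = [g for g in expressed_lnc if g not in set(sig_lnc_ids)]
    cons = conservation_compare(conservation, sig_lnc_ids, background_lnc)

    spec = specificity_scores(norm_lnc)
    spec.to_tsv(outdir / "specificity_lncrna.tsv")
    sig_scores = spec.max_score.loc[sig_lnc_ids].dropna()
    bg_scores = spec.max_score.loc[background_lnc].dropna()
    spec_test = rank_sum_test(
        sig_scores.to_numpy(), bg_scores.to_numpy(), alternative="greater"
    )

    reference_set = (
        sorted(
            {
                g
                for plan in atlas.truth.signature_plan.values()
                for g in plan["genes"]
                if annotation[g].biotype == "coding"
            }
        )
        if atlas is not None
        else sorted({g for t in sig_coding.cell_types for g in sig_coding.genes_for(t)})
    )
    overlap, overlap_p = neighbor_signature_overlap(
        adjacency, sig_lnc, reference_set, universe_size=summary["inputs"]["n_coding"]
    )
    summary["lncrna"] = {
        "adjacency_proportion_overall": (
            float(n_adj / n_sig_lnc_total) if n_sig_lnc_total else float("nan")
        ),
        "conservation_delta_median": cons.delta_median,
        "conservation_p": cons.p,
        "specificity_delta_median": float(
            sig_scores.median() - bg_scores.median()
        ),
        "specificity_p": spec_test.p,
        "neighbor_reference_overlap": overlap,
        "neighbor_reference_overlap_p": overlap_p,
    }

    # ---- regulon activity -----------------------------------------------
    logger.info("stage regulons")
    ras = ras_matrix(
        norm_coding, regulons, top_fraction=config.regulons["top_fraction"]
    )
    ras.to_csv(outdir / "ras.tsv", sep="\t")
    binarized = binarize_ras(ras)
    cluster_labels = norm_coding.obs["cell_type"].map(families)
    states = cluster_regulon_states(
        binarized,
        cluster_labels,
        min_on_fraction=config.regulons["min_on_fraction"],
        max_other_on=config.regulons["max_other_on"],
    )
    states.to_tsv(outdir / "regulon_states.tsv")
    novel = flag_novel_regulons(states, canonical)
    summary["regulons"] = {
        "n_scored": int(ras.shape[1]),
        "n_activated": len(states.activated_regulons()),
        "n_specific": int(sum(len(v) for v in states.specific.values())),
        "n_novel": len(novel),
        "novel": sorted(novel),
    }

    # ---- projection ------------------------------------------------------
    logger.info("stage projection")
    proj = self_projection_accuracy(
        norm_coding,
        n_folds=config.projection["n_folds"],
        seed=config.seed,
        n_features=config.projection["n_features"],
        threshold=config.projection["threshold"],
    )
    proj.per_type.to_csv(outdir / "self_projection.tsv", sep="\t")
    summary["projection"] = {
        "overall_accuracy": proj.overall_accuracy,
        "fraction_types_above_90": float(
            (proj.per_type["accuracy"] >= 0.9).mean()
        ),
    }

    # ---- ground-truth evaluation (simulated runs only) -------------------
    if atlas is not None:
        prec_c, rec_c = signature_recovery(
            sig_coding, atlas.truth, annotation, "coding"
        )
        prec_l, rec_l = signature_recovery(sig_lnc, atlas.truth, annotation, "lncRNA")
        planted_fail = set(atlas.truth.qc_fail_cells)
        removed = set(qc.report.removed_mapping_rate)
        summary["truth_eval"] = {
            "signature_precision_coding": prec_c,
            "signature_recall_coding": rec_c,
            "signature_precision_lncrna": prec_l,
            "signature_recall_lncrna": rec_l,
            "qc_fail_recovered": sorted(planted_fail) == sorted(removed),
            "coupling_fraction_planted": atlas.config.coupling_fraction,
        }
        atlas.truth.to_json(outdir / "truth.json")

    path = outdir / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("wrote %s", path)
    return outdir
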