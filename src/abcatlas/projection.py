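"""Reference-based cell-type prediction by centroid cosine similarity.

A reference model holds, per cell type, the mean expression centroid over
a selected feature set (top per-type genes from one-vs-rest differential
testing). A query cell is assigned to the centroid with the highest cosine
similarity when that similarity reaches the unassignment threshold
(default 0.7, the established default of cluster-level projection methods);
otherwise it is reported UNASSIGNED. Self-projection accuracy — assigning
each reference cell from a model trained without it — estimates annotation
accuracy; UNASSIGNED counts as incorrect.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .signatures import find_signatures

UNASSIGNED = "UNASSIGNED"
DEFAULT_SIMILARITY_THRESHOLD = 0.7
_MIN_FEATURES = 10


@dataclass
class ReferenceModel:
    """Per-type centroids over a fixed feature set."""

    features: list[str]
    centroids: pd.DataFrame  # cell types x features
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD

    def __post_init__(self) -> None:
        if len(self.features) < _MIN_FEATURES:
            raise ValueError(
                f"reference needs at least {_MIN_FEATURES} features, "
                f"got {len(self.features)}"
            )
        if list(self.centroids.columns) != list(self.features):
            raise ValueError("centroid columns must match the feature list")
        if (self.centroids.values < 0).any():
            raise ValueError("centroids must be non-negative")
        zero = self.centroids.index[(self.centroids.values == 0).all(axis=1)]
        if len(zero):
            raise ValueError(f"degenerate all-zero centroid for type {zero[0]!r}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.centroids.index)

    def save(self, centroids_tsv: str | Path, meta_json: str | Path) -> None:
        self.centroids.to_csv(centroids_tsv, sep="\t")
        Path(meta_json).write_text(
            json.dumps(
                {
                    "features": self.features,
                    "similarity_threshold": self.similarity_threshold,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, centroids_tsv: str | Path, meta_json: str | Path) -> "ReferenceModel":
        meta = json.loads(Path(meta_json).read_text())
        centroids = pd.read_csv(centroids_tsv, sep="\t", index_col=0)
        return cls(
            features=meta["features"],
            centroids=centroids[meta["features"]],
            similarity_threshold=meta["similarity_threshold"],
        )


def build_reference(
    norm: ad.AnnData,
    groupby: str = "cell_type",
    n_features: int = 500,
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> ReferenceModel:
    """Build centroids from a labeled log-normalized matrix.

    Features are chosen round-robin from the per-type gene rankings by
    q-value (then fold change) of the one-vs-rest test, until ``n_features``
    distinct genes are collected. If ``n_features`` is at least the gene
    count, all genes are used (with a warning). Centroids are per-type
    means: with sparse, dropout-heavy log expression the per-gene median
    over a few dozen cells is close to a coin-flip between zero and the
    detected level, whereas the mean averages dropout away.
    """
    if groupby not in norm.obs:
        raise ValueError(f"norm.obs lacks column {groupby!r}")
    labels = norm.obs[groupby]
    if labels.nunique() < 2:
        raise ValueError("need at least two cell types")
    if n_features >= norm.n_vars:
        warnings.warn(
            f"n_features={n_features} >= {norm.n_vars} genes; using all genes"
        )
        features = list(norm.var_names)
    else:
        ranked = find_signatures(norm, groupby=groupby, top_n=norm.n_vars)
        per_type = [
            ranked.genes_for(cell_type) for cell_type in ranked.cell_types
        ]
        features_seen: dict[str, None] = {}
        depth = 0
        while len(features_seen) < n_features and any(
            depth < len(lst) for lst in per_type
        ):
            for lst in per_type:
                if depth < len(lst):
                    features_seen.setdefault(lst[depth], None)
                    if len(features_seen) >= n_features:
                        break
            depth += 1
        features = list(features_seen)
        if len(features) < _MIN_FEATURES:
            # degenerate rankings (e.g. near-constant matrix): fall back to
            # the most variable genes so a model can still be built
            variances = np.asarray(norm.X, dtype=float).var(axis=0)
            order = np.argsort(-variances, kind="stable")
            features = [norm.var_names[i] for i in order[:n_features]]

    expr = pd.DataFrame(
        np.asarray(norm.X, dtype=float), index=norm.obs_names, columns=norm.var_names
    )[features]
    centroids = expr.groupby(labels, observed=True).mean()
    centroids = centroids.sort_index()
    return ReferenceModel(
        features=features,
        centroids=centroids,
        similarity_threshold=similarity_threshold,
    )


@dataclass
class ProjectionResult:
    """Assigned type (or UNASSIGNED) and best similarity per query cell."""

    assignments: pd.DataFrame  # columns: assigned, similarity, best_type
    threshold: float

    def accuracy(self, true_labels: pd.Series) -> float:
        """Fraction of cells assigned their true label (UNASSIGNED wrong)."""
        truth = true_labels.loc[self.assignments.index]
        return float((self.assignments["assigned"] == truth).mean())

    def to_tsv(self, path: str | Path) -> None:
        self.assignments.to_csv(path, sep="\t")


def project(
    query: ad.AnnData,
    reference: ReferenceModel,
    threshold: float | None = None,
) -> ProjectionResult:
    """Project query cells onto the reference centroids.

    Cosine similarity is computed over the intersection of query genes and
    reference features, which must cover at least half of the features.
    The argmax centroid is assigned when its similarity reaches the
    threshold; exact ties break by the reference's fixed type order (and
    are reported in a ``tie`` column). Cells with an empty expression
    vector over the shared features are UNASSIGNED with similarity NaN.
    """
    threshold = reference.similarity_threshold if threshold is None else threshold
    shared = [f for f in reference.features if f in set(query.var_names)]
    if not shared:
        raise ValueError("query shares no genes with the reference features")
    if len(shared) < 0.5 * len(reference.features):
        raise ValueError(
            f"query covers only {len(shared)}/{len(reference.features)} "
            "reference features (< 50%)"
        )
    expr = pd.DataFrame(
        np.asarray(query.X, dtype=float), index=query.obs_names, columns=query.var_names
    )[shared].to_numpy()
    cents = reference.centroids[shared].to_numpy()

    q_norm = np.linalg.norm(expr, axis=1)
    c_norm = np.linalg.norm(cents, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sims = (expr @ cents.T) / np.outer(q_norm, c_norm)
    sims = np.where(np.isfinite(sims), sims, np.nan)

    types = np.array(reference.cell_types)
    all_nan = np.all(np.isnan(sims), axis=1)
    best_idx = np.zeros(len(expr), dtype=int)
    best_idx[~all_nan] = np.nanargmax(sims[~all_nan], axis=1)
    best_sim = np.where(all_nan, np.nan, sims[np.arange(len(expr)), best_idx])
    ties = (sims == best_sim[:, None]).sum(axis=1) > 1
    assigned = np.where(
        ~all_nan & (best_sim >= threshold), types[best_idx], UNASSIGNED
    )
    frame = pd.DataFrame(
        {
            "assigned": assigned,
            "similarity": best_sim,
            "best_type": types[best_idx],
            "tie": ties,
        },
        index=query.obs_names,
    )
    frame.loc[all_nan, "best_type"] = UNASSIGNED
    return ProjectionResult(assignments=frame, threshold=threshold)


@dataclass
class SelfProjection:
    overall_accuracy: float
    per_type: pd.DataFrame  # n, n_correct, accuracy, unassigned_rate
    predictions: pd.DataFrame


def self_projection_accuracy(
    norm: ad.AnnData,
    groupby: str = "cell_type",
    n_folds: int = 5,
    seed: int = 0,
    n_features: int = 500,
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> SelfProjection:
    """Stratified k-fold self-projection accuracy.

    Every cell is predicted by a reference built without its fold. Types
    with fewer than ``n_folds`` cells are evaluated leave-one-out instead
    (with a warning). UNASSIGNED predictions count as incorrect.
    """
    labels = norm.obs[groupby]
    counts = labels.value_counts()
    small_types = set(counts.index[counts < n_folds])
    if small_types:
        warnings.warn(
            f"types with < {n_folds} cells evaluated leave-one-out: "
            f"{sorted(small_types)}"
        )
    big_mask = (~labels.isin(small_types)).to_numpy()

    pred_frames: list[pd.DataFrame] = []
    big = norm[big_mask]
    if big.n_obs:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        y = big.obs[groupby].to_numpy()
        for train_idx, test_idx in skf.split(np.zeros(big.n_obs), y):
            ref = build_reference(
                big[train_idx].copy(),
                groupby=groupby,
                n_features=n_features,
                similarity_threshold=threshold,
            )
            result = project(big[test_idx].copy(), ref)
            pred_frames.append(result.assignments)
    # leave-one-out for undersized types, against the full remainder
    for cell in norm.obs_names[~big_mask]:
        rest = norm[norm.obs_names != cell].copy()
        ref = build_reference(
            rest, groupby=groupby, n_features=n_features,
            similarity_threshold=threshold,
        )
        pred_frames.append(project(norm[[cell]].copy(), ref).assignments)

    predictions = pd.concat(pred_frames).loc[norm.obs_names]
    truth = labels.loc[predictions.index]
    correct = predictions["assigned"] == truth
    per_type = pd.DataFrame(
        {
            "n": truth.groupby(truth).size(),
            "n_correct": correct.groupby(truth.to_numpy()).sum(),
            "accuracy": correct.groupby(truth.to_numpy()).mean(),
            "unassigned_rate": (
                (predictions["assigned"] == UNASSIGNED)
                .groupby(truth.to_numpy())
                .mean()
            ),
        }
    )
    per_type.index.name = groupby
    return SelfProjection(
        overall_accuracy=float(correct.mean()),
        per_type=per_type.sort_index(),
        predictions=predictions,
    )
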