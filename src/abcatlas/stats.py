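"""Statistical primitives: Wilcoxon rank-sum test and BH FDR control.

The rank-sum (Mann-Whitney) test is the workhorse of every differential
comparison in this package, so it is implemented here rather than imported:

* for pooled sample sizes up to :data:`EXACT_ENUMERATION_LIMIT` the exact
  null distribution of U is obtained by enumerating every assignment of the
  pooled (mid)ranks to the first group — correct with or without ties;
* for larger samples the normal approximation is used with midranks,
  tie-corrected variance and a 0.5 continuity correction.

A vectorized variant (:func:`rank_sum_matrix`) applies the large-sample test
to every column of a cells x genes matrix at once; it is the engine behind
one-vs-rest signature calling and pairwise DEG counting.
"""
from __future__ import annotations

from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps

EXACT_ENUMERATION_LIMIT = 12

_ALTERNATIVES = ("two-sided", "greater")


class RankSumResult(NamedTuple):
    """Mann-Whitney U statistic (of the first sample) and its p-value."""

    u: float
    p: float


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their midrank."""
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    # boundaries of runs of equal values
    boundaries = np.flatnonzero(np.r_[True, sorted_vals[1:] != sorted_vals[:-1]])
    run_ends = np.r_[boundaries[1:], len(pooled)]
    for lo, hi in zip(boundaries, run_ends):
        ranks[order[lo:hi]] = (lo + 1 + hi) / 2.0
    return ranks


def _exact_p(ranks: np.ndarray, n1: int, u_obs: float, alternative: str) -> float:
    """Exact p by enumerating every n1-subset of the pooled ranks."""
    n = len(ranks)
    offset = n1 * (n1 + 1) / 2.0
    us = np.array(
        [sum(c) - offset for c in combinations(ranks, n1)], dtype=float
    )
    total = len(us)
    eps = 1e-9
    if alternative == "greater":
        return float(np.count_nonzero(us >= u_obs - eps) / total)
    p_ge = np.count_nonzero(us >= u_obs - eps) / total
    p_le = np.count_nonzero(us <= u_obs + eps) / total
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def _tie_term(pooled_sorted: np.ndarray) -> float:
    """Sum of t^3 - t over runs of tied values."""
    boundaries = np.flatnonzero(
        np.r_[True, pooled_sorted[1:] != pooled_sorted[:-1]]
    )
    t = np.diff(np.r_[boundaries, len(pooled_sorted)]).astype(float)
    return float(np.sum(t**3 - t))


def _approx_p(
    u_obs: float, n1: int, n2: int, tie_term: float, alternative: str
) -> float:
    n = n1 + n2
    mean = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # every observation tied
        return 1.0
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (u_obs - mean - 0.5) / sd
        return float(special.ndtr(-z))
    z = (abs(u_obs - mean) - 0.5) / sd
    return float(min(1.0, 2.0 * special.ndtr(-max(z, 0.0))))


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> RankSumResult:
    """Wilcoxon rank-sum test of ``x`` versus ``y``.

    Parameters
    ----------
    x, y
        The two samples; each must be non-empty.
    alternative
        ``"two-sided"`` or ``"greater"`` (x stochastically larger than y).

    Returns
    -------
    RankSumResult
        The Mann-Whitney U of ``x`` and the p-value. Exact (enumeration)
        when ``len(x) + len(y) <= 12``, normal approximation with tie and
        continuity corrections otherwise.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if n1 + n2 <= EXACT_ENUMERATION_LIMIT:
        p = _exact_p(ranks, n1, u_obs, alternative)
    else:
        p = _approx_p(u_obs, n1, n2, _tie_term(np.sort(pooled)), alternative)
    return RankSumResult(u=u_obs, p=p)


def _column_tie_terms(matrix: np.ndarray) -> np.ndarray:
    """Per-column sum of t^3 - t over tied runs, fully vectorized."""
    n, g = matrix.shape
    srt = np.sort(matrix, axis=0)
    flat = srt.T.ravel()  # column-contiguous
    col = np.repeat(np.arange(g), n)
    change = np.r_[True, (flat[1:] != flat[:-1]) | (col[1:] != col[:-1])]
    run_starts = np.flatnonzero(change)
    t = np.diff(np.r_[run_starts, flat.size]).astype(float)
    out = np.zeros(g)
    np.add.at(out, col[run_starts], t**3 - t)
    return out


def rank_sum_matrix(
    matrix: np.ndarray, mask: np.ndarray, alternative: str = "two-sided"
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise rank-sum test of rows in ``mask`` against the rest.

    Large-sample normal approximation with midranks, tie correction and
    continuity correction, applied independently to every column of the
    (observations x variables) ``matrix``. Returns ``(U, p)`` arrays, one
    entry per column.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    matrix = np.asarray(matrix, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n = matrix.shape[0]
    n1 = int(mask.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    ranks = sps.rankdata(matrix, axis=0, method="average")
    r1 = ranks[mask].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    mean = n1 * n2 / 2.0
    tie = _column_tie_terms(matrix)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        if alternative == "greater":
            z = (u - mean - 0.5) / sd
            p = special.ndtr(-z)
        else:
            z = (np.abs(u - mean) - 0.5) / sd
            p = np.minimum(1.0, 2.0 * special.ndtr(-np.maximum(z, 0.0)))
    p = np.where(sd == 0, 1.0, p)
    return u, p


def rank_sum_one_vs_rest(
    matrix: np.ndarray,
    labels: Sequence,
    alternative: str = "two-sided",
) -> dict[object, tuple[np.ndarray, np.ndarray]]:
    """Column-wise one-vs-rest rank-sum tests for every distinct label.

    Equivalent to calling :func:`rank_sum_matrix` once per label, but the
    pooled ranking and tie corrections are computed a single time, since
    every one-vs-rest comparison shares them. Returns ``{label: (U, p)}``.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    n = matrix.shape[0]
    ranks = sps.rankdata(matrix, axis=0, method="average")
    tie = _column_tie_terms(matrix)
    out: dict[object, tuple[np.ndarray, np.ndarray]] = {}
    for label in pd.unique(labels):
        mask = labels == label
        n1 = int(mask.sum())
        n2 = n - n1
        if n1 == 0 or n2 == 0:
            raise ValueError("both groups must be non-empty")
        r1 = ranks[mask].sum(axis=0)
        u = r1 - n1 * (n1 + 1) / 2.0
        mean = n1 * n2 / 2.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
        sd = np.sqrt(np.maximum(var, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            if alternative == "greater":
                z = (u - mean - 0.5) / sd
                p = special.ndtr(-z)
            else:
                z = (np.abs(u - mean) - 0.5) / sd
                p = np.minimum(1.0, 2.0 * special.ndtr(-np.maximum(z, 0.0)))
        p = np.where(sd == 0, 1.0, p)
        out[label] = (u, p)
    return out


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Input p-values must lie in (0, 1]. The output preserves input order and
    is monotone non-decreasing in p-rank.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeometric_overlap_test(
    overlap: int, n_a: int, n_b: int, universe: int
) -> float:
    """Upper-tail hypergeometric p for the overlap between two gene sets.

    Probability of drawing ``overlap`` or more members of a reference set of
    size ``n_b`` when sampling ``n_a`` genes from a universe of ``universe``.
    """
    if universe < n_a or universe < n_b:
        raise ValueError("universe smaller than one of the sets")
    if overlap < 0 or overlap > min(n_a, n_b):
        raise ValueError("overlap outside feasible range")
    return float(sps.hypergeom.sf(overlap - 1, universe, n_b, n_a))
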