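"""Filter-based gene selection: per-gene t-test, deterministic Relief, and
median-distance ranking of gene pairs.

All rankers operate on a genes x samples array of M-values computed from the
*training* samples of a cross-validation split only.  Everything is
deterministic: ties break by ascending gene index, and the Relief variant
visits every observation exactly once instead of sampling with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GENE_COUNT_GRID", "RankedGenes", "RankedPairs", "ttest_rank",
           "bonferroni_threshold", "relief_rank", "paired_distance_rank",
           "expand_pairs_to_genes", "select_genes", "SELECTORS"]

#: the 21 gene-count settings evaluated by the benchmark
GENE_COUNT_GRID = (2, 12, 22, 32, 42, 52, 62, 72, 82, 92, 100,
                   150, 200, 300, 400, 500, 600, 700, 800, 900, 1000)

SELECTORS = ("ttest", "relief", "paired_distance")


@dataclass
class RankedGenes:
    """Gene indices sorted best-first with the matching score per gene."""

    order: np.ndarray    # gene indices, best first
    scores: np.ndarray   # score aligned with ``order``


@dataclass
class RankedPairs:
    """Gene-pair ranking: pairs sorted by decreasing class-median distance."""

    pairs: np.ndarray     # (n_pairs, 2) gene indices, i < j within a pair
    distances: np.ndarray
    delta: np.ndarray     # per-gene class-median difference (full gene axis)


def _split_classes(X: np.ndarray, labels: np.ndarray):
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {len(classes)}")
    return X[:, labels == classes[0]], X[:, labels == classes[1]]


def ttest_rank(X: np.ndarray, labels: np.ndarray,
               equal_var: bool = False) -> RankedGenes:
    """Rank genes by two-sided two-sample t-test p-value, smallest first.

    Welch's unequal-variance form by default.  Genes whose statistic is
    undefined (zero variance in both classes) get p = 1 and sort last.
    """
    X = np.asarray(X, dtype=float)
    a, b = _split_classes(X, labels)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each class needs at least two samples for a t-test")
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.where(np.isnan(p), 1.0, p)
    order = np.lexsort((np.arange(len(p)), p))
    return RankedGenes(order=order, scores=p[order])


def bonferroni_threshold(n_genes: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_genes."""
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    return alpha / n_genes


def relief_rank(X: np.ndarray, labels: np.ndarray) -> RankedGenes:
    """Deterministic Relief: every observation contributes exactly once.

    For each observation the nearest same-class neighbour (hit) and nearest
    other-class neighbour (miss) are found by Euclidean distance over all
    genes; each gene's weight accumulates (diff-to-miss - diff-to-hit) / m,
    where diff is the absolute difference scaled by the gene's observed
    range.  Higher weight = better separator.  An observation whose class
    has no other member contributes only its miss term.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("exactly two classes required")
    n_genes, m = X.shape
    rng_range = X.max(axis=1) - X.min(axis=1)
    scale = np.where(rng_range > 0, rng_range, np.inf)  # constant gene -> diff 0

    # pairwise Euclidean distances between observations
    XT = X.T
    d2 = np.sum((XT[:, None, :] - XT[None, :, :]) ** 2, axis=2)
    np.fill_diagonal(d2, np.inf)

    W = np.zeros(n_genes)
    for i in range(m):
        same = labels == labels[i]
        row = d2[i]
        miss_pool = np.where(~same)[0]
        j_miss = miss_pool[np.argmin(row[miss_pool])]
        W += np.abs(X[:, i] - X[:, j_miss]) / scale / m
        hit_pool = np.where(same)[0]
        hit_pool = hit_pool[hit_pool != i]
        if len(hit_pool) == 0:
            continue  # singleton class: no hit term for this observation
        j_hit = hit_pool[np.argmin(row[hit_pool])]
        W -= np.abs(X[:, i] - X[:, j_hit]) / scale / m
    order = np.lexsort((np.arange(n_genes), -W))
    return RankedGenes(order=order, scores=W[order])


def paired_distance_rank(X: np.ndarray, labels: np.ndarray,
                         n_top: int = 1000) -> RankedPairs:
    """Rank gene pairs by the distance between their class-median points.

    Candidates are the union of the ``n_top`` highest-variance genes and the
    ``n_top`` highest-|mean| genes.  For each candidate the difference of
    class medians delta_g is computed; a pair (i, j) scores
    sqrt(delta_i**2 + delta_j**2), i.e. the Euclidean distance between the
    two class-median points in the pair's plane.  Pairs sort by decreasing
    distance, ties by ascending (i, j).
    """
    X = np.asarray(X, dtype=float)
    n_genes = X.shape[0]
    var = X.var(axis=1)
    amean = np.abs(X.mean(axis=1))
    if n_genes > n_top:
        by_var = np.lexsort((np.arange(n_genes), -var))[:n_top]
        by_mean = np.lexsort((np.arange(n_genes), -amean))[:n_top]
        cand = np.union1d(by_var, by_mean)
    else:
        cand = np.arange(n_genes)
    if len(cand) < 2:
        raise ValueError("fewer than two candidate genes")

    a, b = _split_classes(X, labels)
    delta = np.full(n_genes, np.nan)
    delta[cand] = np.median(a[cand], axis=1) - np.median(b[cand], axis=1)

    d2c = delta[cand] ** 2
    ii, jj = np.triu_indices(len(cand), k=1)
    d = np.sqrt(d2c[ii] + d2c[jj])
    gi, gj = cand[ii], cand[jj]
    order = np.lexsort((gj, gi, -d))
    pairs = np.column_stack([gi[order], gj[order]])
    return RankedPairs(pairs=pairs, distances=d[order], delta=delta)


def expand_pairs_to_genes(ranked: RankedPairs, N: int) -> np.ndarray:
    """Collect the top N distinct genes by walking the pair ranking.

    Pairs are visited best-first; each pair appends its not-yet-included
    genes.  When a pair would overflow N, its larger-|delta| gene is taken
    first.  If fewer than N distinct genes exist, all are returned with a
    warning.
    """
    if N < 1:
        raise ValueError("N must be positive")
    seen: dict[int, None] = {}
    adelta = np.abs(ranked.delta)
    for i, j in ranked.pairs:
        first, second = (i, j) if adelta[i] >= adelta[j] else (j, i)
        for g in (int(first), int(second)):
            if g not in seen:
                seen[g] = None
            if len(seen) == N:
                return np.fromiter(seen.keys(), dtype=int)
    warnings.warn(f"only {len(seen)} distinct genes available, requested {N}",
                  stacklevel=2)
    return np.fromiter(seen.keys(), dtype=int)


def select_genes(method: str, X: np.ndarray, labels: np.ndarray,
                 N: int) -> np.ndarray:
    """Top-N gene indices of the chosen ranker, computed on training data.

    ``N`` must belong to the benchmark's gene-count grid.
    """
    if N not in GENE_COUNT_GRID:
        raise ValueError(f"N={N} is not on the gene-count grid")
    if method == "ttest":
        return ttest_rank(X, labels).order[:N]
    if method == "relief":
        return relief_rank(X, labels).order[:N]
    if method == "paired_distance":
        return expand_pairs_to_genes(paired_distance_rank(X, labels), N)
    raise ValueError(f"unknown gene selection method {method!r}")
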