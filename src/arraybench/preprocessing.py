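"""Flag handling, missingness filtering, SVD imputation and duplicate-gene
averaging.

The canonical order is ``flags_to_missing`` -> ``filter_missing`` ->
``svd_impute`` -> ``average_duplicates`` (see :func:`preprocess`); each
step's output satisfies the next step's preconditions.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = ["flags_to_missing", "filter_missing", "svd_impute",
           "average_duplicates", "preprocess"]

log = logging.getLogger(__name__)


def flags_to_missing(matrix: ExpressionMatrix,
                     flags: np.ndarray | None = None) -> ExpressionMatrix:
    """Convert flagged spots to missing values.

    ``flags`` defaults to the flag matrix attached by the normalizer.  The
    output mask is a superset of the input mask; flags on already-missing
    entries change nothing.
    """
    if flags is None:
        flags = matrix.flags
    if flags is None:
        return matrix.copy()
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != matrix.values.shape:
        raise ValueError("flags are misaligned with the matrix")
    out = matrix.copy()
    out.values[flags] = np.nan
    out.flags = None
    return out


def filter_missing(matrix: ExpressionMatrix, sample_max: float = 0.5,
                   gene_max: float = 0.3) -> ExpressionMatrix:
    """Keep samples with less than ``sample_max`` and genes with less than
    ``gene_max`` missing values, evaluated simultaneously.

    Both missing fractions are computed once on the input matrix, then rows
    and columns are dropped in a single pass, so removing a bad sample does
    not rescue a bad gene or vice versa.  The thresholds are strict: a gene
    missing exactly 30% is removed.
    """
    if not (0 < sample_max <= 1 and 0 < gene_max <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    miss = matrix.missing_mask
    gene_frac = miss.mean(axis=1)
    sample_frac = miss.mean(axis=0)
    keep_genes = gene_frac < gene_max
    keep_samples = sample_frac < sample_max
    if not keep_genes.any() or not keep_samples.any():
        raise ValueError("filtering removed every gene or every sample")
    out = ExpressionMatrix(
        values=matrix.values[np.ix_(keep_genes, keep_samples)].copy(),
        gene_ids=[g for g, k in zip(matrix.gene_ids, keep_genes) if k],
        meta=[m for m, k in zip(matrix.meta, keep_samples) if k],
        flags=None if matrix.flags is None
        else matrix.flags[np.ix_(keep_genes, keep_samples)].copy(),
    )
    log.info("filter_missing: dropped %d genes and %d samples",
             int((~keep_genes).sum()), int((~keep_samples).sum()))
    return out


def svd_impute(matrix: ExpressionMatrix, k: int = 10, tol: float = 1e-2,
               max_iter: int = 100) -> ExpressionMatrix:
    """Impute missing values from the k most significant eigengenes.

    Iterative scheme: initialize missing entries with row (gene) medians,
    compute the rank-k SVD approximation, replace the missing entries with
    the approximation and repeat until the relative Frobenius change of the
    matrix falls below ``tol``.  Observed entries are never altered.
    """
    X = matrix.values.copy()
    miss = np.isnan(X)
    if not miss.any():
        return matrix.copy()
    k = int(min(k, min(X.shape) - 1))
    if k < 1:
        raise ValueError("k must be at least 1 (and the matrix at least 2x2)")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_med = np.nanmedian(X, axis=1)
    row_med = np.where(np.isnan(row_med), 0.0, row_med)
    X[miss] = np.broadcast_to(row_med[:, None], X.shape)[miss]

    converged = False
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        approx = (U[:, :k] * s[:k]) @ Vt[:k]
        new = X.copy()
        new[miss] = approx[miss]
        denom = max(np.linalg.norm(X), 1e-12)
        change = np.linalg.norm(new - X) / denom
        X = new
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn("svd_impute did not converge; returning the last iterate",
                      RuntimeWarning, stacklevel=2)

    out = matrix.copy()
    out.values = X
    return out


def average_duplicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse repeated gene IDs to one row by averaging, ignoring missing
    replicates; the result is missing only where all replicates are missing.

    Unique-ID row order follows first appearance.
    """
    ids = pd.Index(matrix.gene_ids)
    if ids.is_unique:
        return matrix.copy()
    df = pd.DataFrame(matrix.values, index=ids)
    grouped = df.groupby(level=0, sort=False).mean()  # skips NaN by default
    return ExpressionMatrix(
        values=grouped.to_numpy(),
        gene_ids=list(grouped.index),
        meta=list(matrix.meta),
        flags=None,
    )


def preprocess(matrix: ExpressionMatrix, sample_max: float = 0.5,
               gene_max: float = 0.3, k: int = 10) -> ExpressionMatrix:
    """Run the full preprocessing chain on a normalized matrix."""
    m = flags_to_missing(matrix)
    m = filter_missing(m, sample_max=sample_max, gene_max=gene_max)
    if m.missing_mask.any():
        m = svd_impute(m, k=k)
    m = average_duplicates(m)
    return m
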