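"""Two-channel normalization: raw M-values, global and print-tip MA-loess,
each with or without local background correction.

The five variants are numbered as in the benchmark configuration:

====  =========================================================
id    meaning
====  =========================================================
0     raw data (M from uncorrected intensities, no smoothing)
1     print-tip MA-loess, no background correction
2     print-tip MA-loess, background correction
3     global MA-loess, no background correction
4     global MA-loess, background correction
====  =========================================================

Print-tip variants (1, 2) require data with more than one print-tip block;
Agilent-like single-block layouts only support 0, 3 and 4.

Each array is normalized independently (nothing crosses samples), so
normalization before any cross-validation split leaks no information.
"""

from __future__ import annotations

import logging

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import ExpressionMatrix, SampleMeta, SpotTable

__all__ = ["background_correct", "compute_MA", "loess_normalize",
           "normalize_dataset", "NORMALIZATION_IDS"]

log = logging.getLogger(__name__)

NORMALIZATION_IDS = (0, 1, 2, 3, 4)

#: below this many usable points a loess fit per group is not attempted
MIN_LOESS_POINTS = 10


def background_correct(spots: SpotTable) -> SpotTable:
    """Subtract each spot's local background from its foreground, per channel.

    A spot where either corrected channel is nonpositive becomes missing
    (NaN in both channels) rather than an error.
    """
    out = spots.copy()
    R = spots.R_fg - spots.R_bg
    G = spots.G_fg - spots.G_bg
    bad = ~((R > 0) & (G > 0))
    R = np.where(bad, np.nan, R)
    G = np.where(bad, np.nan, G)
    out.R_fg, out.G_fg = R, G
    out.R_bg = np.zeros_like(spots.R_bg)
    out.G_bg = np.zeros_like(spots.G_bg)
    return out


def compute_MA(spots: SpotTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-spot M = log2(R/G) and A = 0.5*log2(R*G) from foreground
    intensities; nonpositive or missing intensities yield NaN."""
    R = np.asarray(spots.R_fg, dtype=float)
    G = np.asarray(spots.G_fg, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = (R > 0) & (G > 0)
        M = np.where(ok, np.log2(np.where(ok, R, 1.0) / np.where(ok, G, 1.0)), np.nan)
        A = np.where(ok, 0.5 * np.log2(np.where(ok, R * G, 1.0)), np.nan)
    return M, A


def _loess_residual(M: np.ndarray, A: np.ndarray, span: float) -> np.ndarray:
    """Residuals of a robust locally weighted linear regression of M on A."""
    n = len(M)
    if n < MIN_LOESS_POINTS:
        log.info("loess group with %d points: subtracting the median instead", n)
        return M - np.median(M)
    # delta: merge near-identical abscissae for speed on dense arrays
    delta = 0.005 * (np.max(A) - np.min(A))
    fit = lowess(M, A, frac=span, it=3, delta=delta, return_sorted=False)
    return M - fit


def loess_normalize(M: np.ndarray, A: np.ndarray,
                    groups: np.ndarray | None = None,
                    span: float = 0.3) -> np.ndarray:
    """Subtract a loess fit of M on A; one fit per group when grouped.

    Missing entries (NaN in M or A) are excluded from the fit and passed
    through unchanged.  Groups with too few usable points fall back to
    subtracting the group median of M.
    """
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    if M.shape != A.shape:
        raise ValueError("M and A must have the same length")
    out = M.copy()
    ok = ~(np.isnan(M) | np.isnan(A))
    if groups is None:
        if ok.any():
            out[ok] = _loess_residual(M[ok], A[ok], span)
        return out
    groups = np.asarray(groups)
    if groups.shape != M.shape:
        raise ValueError("groups must have the same length as M")
    for g in np.unique(groups):
        sel = ok & (groups == g)
        if sel.any():
            out[sel] = _loess_residual(M[sel], A[sel], span)
    return out


def normalize_dataset(spots: list[SpotTable], meta: list[SampleMeta],
                      method: int, span: float = 0.3) -> ExpressionMatrix:
    """Apply one of the five normalization variants to every array.

    Rows of the result are spots (duplicate gene IDs still duplicated);
    columns are samples in ``meta`` order.  Spot flags are carried through
    on the ``flags`` attribute for the preprocessing stage.
    """
    if method not in NORMALIZATION_IDS:
        raise ValueError(f"unknown normalization id {method}")
    if len(spots) != len(meta):
        raise ValueError("one SpotTable per sample required")
    if not spots:
        raise ValueError("empty data set")

    gene_ids = list(spots[0].gene_id)
    n_blocks = spots[0].n_blocks
    if method in (1, 2) and n_blocks < 2:
        raise ValueError(
            f"normalization No {method} is print-tip based and requires more "
            "than one print-tip block; this data set has a single block "
            "(Agilent-like layout)")

    cols = []
    flag_cols = []
    for s in spots:
        if list(s.gene_id) != gene_ids:
            raise ValueError("all arrays must share the same spot layout")
        t = background_correct(s) if method in (2, 4) else s
        M, A = compute_MA(t)
        if method in (1, 2):
            M = loess_normalize(M, A, groups=s.block, span=span)
        elif method in (3, 4):
            M = loess_normalize(M, A, span=span)
        cols.append(M)
        flag_cols.append(np.asarray(s.flag, dtype=bool))

    return ExpressionMatrix(
        values=np.column_stack(cols),
        gene_ids=gene_ids,
        meta=list(meta),
        flags=np.column_stack(flag_cols),
    )
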