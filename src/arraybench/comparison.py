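"""Cross-data-set comparison of method performance.

Works on a *result table*: one row per (data set, combination) with the mean
adjusted error, columns ``D`` (data set), ``M`` (classifier), ``G``
(selector), ``N`` (number of genes), ``No`` (normalization) and ``Eadj``.

Methods (or pairs of methods) are compared within each data set by a paired
one-sided Wilcoxon signed-rank test over all combinations matched on the
remaining factors, then counts of significantly-better data sets are
accumulated into heatmap matrices.  Counts involving the print-tip
normalizations (No 1 / No 2), which are unavailable on single-block data
sets, are rescaled by 7/5 so they remain comparable with methods evaluated
on all seven data sets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FACTORS", "ComparisonMatrix", "SynergyMatrix", "RegressionResult",
           "paired_errors", "wilcoxon_better", "comparison_heatmap",
           "synergy_matrix", "regression_decomposition", "render_heatmap"]

FACTORS = ("No", "G", "N", "M")


@dataclass
class ComparisonMatrix:
    """entries[i, j] = (adjusted) number of data sets where method/pair i is
    significantly better than method/pair j."""

    labels: list
    counts: np.ndarray       # after the 7/5 adjustment (may be non-integer)
    raw_counts: np.ndarray   # integer counts before adjustment
    alpha: float
    n_tests: int


@dataclass
class SynergyMatrix:
    """Square matrix over the two factors' levels: upper-right block holds
    positive counts (pair beats its better member alone), lower-left block
    negative counts (pair is worse than its worse member); cells outside the
    two blocks are NaN."""

    labels: list
    counts: np.ndarray
    factor_pair: tuple
    alpha: float


@dataclass
class RegressionResult:
    adj_r2: float
    anova: pd.DataFrame
    threshold: float
    significant: list = field(default_factory=list)


def _levels(table: pd.DataFrame, factor) -> list:
    if isinstance(factor, str):
        return sorted(table[factor].unique().tolist())
    f1, f2 = factor
    present = table[[f1, f2]].drop_duplicates()
    return sorted(map(tuple, present.to_numpy().tolist()))


def _select(sub: pd.DataFrame, factor, level) -> pd.DataFrame:
    if isinstance(factor, str):
        return sub[sub[factor] == level]
    (f1, f2), (l1, l2) = factor, level
    return sub[(sub[f1] == l1) & (sub[f2] == l2)]


def _rest(factor) -> list[str]:
    used = {factor} if isinstance(factor, str) else set(factor)
    return [f for f in FACTORS if f not in used]


def paired_errors(table: pd.DataFrame, dataset: str, factor,
                  level_a, level_b) -> np.ndarray:
    """Error pairs for two levels of one factor (or factor pair), matched on
    all remaining factors within one data set.

    Combinations existing for only one level are dropped.  Returns an
    (n, 2) array of (error_a, error_b).
    """
    sub = table[table["D"] == dataset]
    keys = _rest(factor)
    a = _select(sub, factor, level_a)[keys + ["Eadj"]]
    b = _select(sub, factor, level_b)[keys + ["Eadj"]]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    return merged[["Eadj_a", "Eadj_b"]].to_numpy()


def wilcoxon_better(pairs: np.ndarray) -> float:
    """One-sided signed-rank p-value for "a has smaller error than b".

    Zero differences are dropped before ranking; if every pair is tied the
    p-value is 1.  The exact null distribution is used for small samples,
    the continuity-corrected normal approximation otherwise.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.size == 0:
        return 1.0
    d = pairs[:, 0] - pairs[:, 1]
    d = d[d != 0.0]
    if len(d) == 0:
        return 1.0
    res = stats.wilcoxon(d, alternative="less", correction=True)
    return float(res.pvalue)


def _involves_printtip(factor, level) -> bool:
    if isinstance(factor, str):
        return factor == "No" and level in (1, 2)
    return any(f == "No" and l in (1, 2) for f, l in zip(factor, level))


def comparison_heatmap(table: pd.DataFrame, factor,
                       alpha_mode: str = "bonferroni") -> ComparisonMatrix:
    """Count, per ordered level pair, the data sets where one level beats
    the other.

    ``alpha_mode``: ``"bonferroni"`` divides 0.05 by the number of Wilcoxon
    tests actually performed in the heatmap (used for individual methods);
    ``"fixed05"`` keeps the 0.05 threshold (used for pairs of methods).
    Counts for levels involving No 1 / No 2 are multiplied by 7/5.
    """
    if alpha_mode not in ("bonferroni", "fixed05"):
        raise ValueError(f"unknown alpha_mode {alpha_mode!r}")
    levels = _levels(table, factor)
    datasets = sorted(table["D"].unique().tolist())
    pvals: dict[tuple, float] = {}
    for d in datasets:
        for la, lb in itertools.permutations(levels, 2):
            pairs = paired_errors(table, d, factor, la, lb)
            if len(pairs) == 0:
                continue
            pvals[(d, la, lb)] = wilcoxon_better(pairs)
    n_tests = len(pvals)
    alpha = 0.05 / n_tests if (alpha_mode == "bonferroni" and n_tests) else 0.05

    k = len(levels)
    raw = np.zeros((k, k), dtype=int)
    for (d, la, lb), p in pvals.items():
        if p < alpha:
            raw[levels.index(la), levels.index(lb)] += 1
    counts = raw.astype(float)
    for i, li in enumerate(levels):
        for j, lj in enumerate(levels):
            if _involves_printtip(factor, li) or _involves_printtip(factor, lj):
                counts[i, j] *= 7.0 / 5.0
    return ComparisonMatrix(labels=levels, counts=counts, raw_counts=raw,
                            alpha=alpha, n_tests=n_tests)


def synergy_matrix(table: pd.DataFrame, factor_pair: tuple[str, str],
                   alpha: float = 0.05) -> SynergyMatrix:
    """Count data sets where a method pair beats its better member alone
    (positive, upper-right block) or trails its worse member (negative,
    lower-left block).

    For a pair (x of factor one, y of factor two): combinations containing
    both are compared, matched on the remaining factors, against the mean
    error of combinations containing only x (over the other levels of factor
    two) and only y respectively.  Which single member is "better"/"worse"
    is decided per data set by the mean over the matched cells.
    """
    f1, f2 = factor_pair
    lv1 = sorted(table[f1].unique().tolist())
    lv2 = sorted(table[f2].unique().tolist())
    datasets = sorted(table["D"].unique().tolist())
    keys = [f for f in FACTORS if f not in (f1, f2)]

    labels = [(f1, l) for l in lv1] + [(f2, l) for l in lv2]
    counts = np.full((len(labels), len(labels)), np.nan)

    for xi, x in enumerate(lv1):
        for yi, y in enumerate(lv2):
            better = worse = 0
            for d in datasets:
                sub = table[table["D"] == d]
                both = sub[(sub[f1] == x) & (sub[f2] == y)][keys + ["Eadj"]]
                x_alone = (sub[(sub[f1] == x) & (sub[f2] != y)]
                           .groupby(keys, as_index=False)["Eadj"].mean())
                y_alone = (sub[(sub[f2] == y) & (sub[f1] != x)]
                           .groupby(keys, as_index=False)["Eadj"].mean())
                merged = both.merge(x_alone, on=keys, suffixes=("", "_x")) \
                             .merge(y_alone, on=keys, suffixes=("", "_y"))
                if len(merged) == 0:
                    continue
                singles = {"Eadj_x": merged["Eadj_x"].mean(),
                           "Eadj_y": merged["Eadj_y"].mean()}
                best = min(singles, key=singles.get)
                worst = max(singles, key=singles.get)
                pair_best = merged[["Eadj", best]].to_numpy()
                pair_worst = merged[[worst, "Eadj"]].to_numpy()
                if wilcoxon_better(pair_best) < alpha:
                    better += 1
                if wilcoxon_better(pair_worst) < alpha:
                    worse += 1
            counts[xi, len(lv1) + yi] = better
            counts[len(lv1) + yi, xi] = -worse
    return SynergyMatrix(labels=labels, counts=counts, factor_pair=factor_pair,
                         alpha=alpha)


def regression_decomposition(table: pd.DataFrame, include_dataset: bool = True,
                             response: str = "Eadj",
                             alpha: float = 0.05) -> RegressionResult:
    """Least-squares decomposition of error variance over the design factors.

    Fits categorical main effects plus all pairwise interactions (the gene
    count N is treated as categorical) and returns the adjusted R-squared
    and sequential ANOVA per-term p-values, flagged against an
    ``alpha / n_terms`` threshold.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    factors = (["D"] if include_dataset else []) + list(FACTORS)
    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f} needs at least two levels")
    mains = [f"C({f})" for f in factors]
    inters = [f"C({a}):C({b})" for a, b in itertools.combinations(factors, 2)]
    formula = f"{response} ~ " + " + ".join(mains + inters)

    model = smf.ols(formula, data=table).fit()
    threshold = alpha / (len(mains) + len(inters))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            anova = sm.stats.anova_lm(model, typ=1)
    except Exception:  # rank-deficient designs can break the ANOVA table
        warnings.warn("ANOVA table unavailable (aliased terms dropped)",
                      stacklevel=2)
        anova = pd.DataFrame()
    significant = []
    if "PR(>F)" in anova.columns:
        significant = [t for t, p in anova["PR(>F)"].items()
                       if t != "Residual" and np.isfinite(p) and p < threshold]
    return RegressionResult(adj_r2=float(model.rsquared_adj), anova=anova,
                            threshold=threshold, significant=significant)


def render_heatmap(matrix: ComparisonMatrix | SynergyMatrix,
                   path: str) -> None:
    """Write a level-plot image of a count matrix with labels and colorbar."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = np.asarray(matrix.counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty matrix")
    labels = [str(l) for l in matrix.labels]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(labels) + 2), max(3, 0.5 * len(labels) + 1)))
    im = ax.imshow(np.ma.masked_invalid(counts), cmap="viridis")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="data sets significantly better")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
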