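"""Patient-aware repeated double cross-validation and permutation testing.

The outer loop (default 5 folds, repeated 10 times = 50 test sets) estimates
generalization error; the inner 10-fold loop, run entirely on the training
portion, tunes any free classifier parameter.  Gene selection happens inside
the outer loop, on training samples only.  Fold construction is patient
aware: all samples of one patient always share a fold, and the number of
distinct patients per fold differs by at most one.

Error rates are reported raw (misclassified fraction) and adjusted --
divided by the theoretical error 2*p*(1-p) of random class assignment given
the full data set's class fractions, so 1.0 means chance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import classifiers, gene_selection
from .containers import ExpressionMatrix, MethodCombo, SampleMeta, labels_of

__all__ = ["FoldPlan", "ComboResult", "PermutationResult", "make_fold_plan",
           "theoretical_error", "adjusted_error", "run_double_cv",
           "permutation_test", "permute_labels"]


@dataclass
class FoldPlan:
    """Outer-CV fold assignments: one row per repeat, one entry per sample."""

    repeats: int
    outer_k: int
    assignments: np.ndarray  # shape (repeats, n_samples), fold index per sample

    def split(self, repeat: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.assignments[repeat] == fold
        return ~test, test


@dataclass
class ComboResult:
    """All outer-CV test-set error rates of one combination on one data set."""

    combo: MethodCombo
    dataset_id: str
    errors: np.ndarray       # raw test-set error rates, len = repeats * outer_k
    adj_errors: np.ndarray
    mean_error: float
    sd_error: float
    mean_adj_error: float
    sd_adj_error: float


@dataclass
class PermutationResult:
    null_values: np.ndarray  # mean adjusted errors under permuted labels
    observed: float          # unpermuted mean adjusted error
    percentile: float        # empirical percentile of observed within the null


def make_fold_plan(meta: list[SampleMeta], repeats: int = 10, outer_k: int = 5,
                   seed: int = 0) -> FoldPlan:
    """Patient-aware fold plan: shuffle patients per repeat, deal them
    round-robin to folds, and let samples follow their patient."""
    patients: list[str] = []
    for m in meta:
        if m.patient_id not in patients:
            patients.append(m.patient_id)
    if len(patients) < outer_k:
        raise ValueError(f"need at least {outer_k} patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    sample_patient = np.array([patients.index(m.patient_id) for m in meta])
    assignments = np.empty((repeats, len(meta)), dtype=int)
    for r in range(repeats):
        order = rng.permutation(len(patients))
        patient_fold = np.empty(len(patients), dtype=int)
        patient_fold[order] = np.arange(len(patients)) % outer_k
        assignments[r] = patient_fold[sample_patient]
    return FoldPlan(repeats=repeats, outer_k=outer_k, assignments=assignments)


def theoretical_error(labels: np.ndarray) -> float:
    """Expected error of random class assignment from the class fractions:
    2*p*(1-p) for a binary problem."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    p = counts[0] / counts.sum()
    return float(2.0 * p * (1.0 - p))


def adjusted_error(raw: float | np.ndarray, labels: np.ndarray):
    """Raw error divided by the random-assignment baseline."""
    return raw / theoretical_error(labels)


def run_double_cv(matrix: ExpressionMatrix, combo: MethodCombo,
                  plan: FoldPlan, seed: int = 0) -> ComboResult:
    """Estimate a combination's error over all outer splits of ``plan``.

    ``matrix`` must already be normalized (per ``combo.normalization``) and
    preprocessed to completeness.  Per outer split: genes are selected on the
    training samples only, any tunable parameter is optimized by inner
    10-fold CV on the training samples with those genes, the model is fitted
    on the full training split and scored on the test split.
    """
    if combo.selector not in gene_selection.SELECTORS:
        raise ValueError(f"unknown selector {combo.selector!r}")
    if not classifiers.applicable(combo.classifier, combo.n_genes):
        raise ValueError(
            f"{combo.classifier} is not applicable at N={combo.n_genes}")
    if np.isnan(matrix.values).any():
        raise ValueError("matrix must be imputed (no missing values) before CV")

    labels = matrix.labels()
    base = theoretical_error(labels)
    values = matrix.values

    rng = np.random.default_rng(seed)
    split_seeds = rng.integers(0, 2**31 - 1,
                               size=(plan.repeats, plan.outer_k))

    errors = []
    for r in range(plan.repeats):
        for f in range(plan.outer_k):
            train, test = plan.split(r, f)
            sel = gene_selection.select_genes(
                combo.selector, values[:, train], labels[train], combo.n_genes)
            model = classifiers.fit(
                combo.classifier, values[np.ix_(sel, train)].T, labels[train],
                seed=int(split_seeds[r, f]))
            pred = model.predict(values[np.ix_(sel, test)].T)
            errors.append(float(np.mean(pred != labels[test])))

    errors = np.array(errors)
    adj = errors / base
    return ComboResult(
        combo=combo, dataset_id="", errors=errors, adj_errors=adj,
        mean_error=float(errors.mean()), sd_error=float(errors.std(ddof=1)),
        mean_adj_error=float(adj.mean()), sd_adj_error=float(adj.std(ddof=1)),
    )


def permute_labels(meta: list[SampleMeta], seed: int) -> np.ndarray:
    """Patient-coherent label shuffle: the patients' class labels are
    permuted across patients, so all samples of a patient stay coherent and
    the overall label multiset is preserved at the patient level."""
    rng = np.random.default_rng(seed)
    patients: list[str] = []
    for m in meta:
        if m.patient_id not in patients:
            patients.append(m.patient_id)
    pat_label = {p: next(m.class_label for m in meta if m.patient_id == p)
                 for p in patients}
    shuffled = rng.permutation([pat_label[p] for p in patients])
    new_map = dict(zip(patients, shuffled))
    return np.array([new_map[m.patient_id] for m in meta], dtype=object)


def permutation_test(matrix: ExpressionMatrix, combo: MethodCombo,
                     n_perms: int, seed: int = 0, repeats: int = 10,
                     outer_k: int = 5) -> PermutationResult:
    """Null distribution of the mean adjusted error under label shuffling.

    Each permutation shuffles class labels patient-coherently, rebuilds the
    fold plan and reruns the double CV.  Returns the null values, the
    unpermuted (observed) value and its empirical percentile.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be positive")
    rng = np.random.default_rng(seed)
    plan_seed, cv_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    perm_seeds = rng.integers(0, 2**31 - 1, size=n_perms)

    plan = make_fold_plan(matrix.meta, repeats=repeats, outer_k=outer_k,
                          seed=plan_seed)
    observed = run_double_cv(matrix, combo, plan, seed=cv_seed).mean_adj_error

    null_values = np.empty(n_perms)
    for i, ps in enumerate(perm_seeds):
        permuted = matrix.with_labels(permute_labels(matrix.meta, int(ps)))
        pplan = make_fold_plan(permuted.meta, repeats=repeats, outer_k=outer_k,
                               seed=plan_seed)
        null_values[i] = run_double_cv(permuted, combo, pplan,
                                       seed=cv_seed).mean_adj_error

    percentile = float(np.mean(null_values <= observed) * 100.0)
    return PermutationResult(null_values=null_values, observed=observed,
                             percentile=percentile)
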