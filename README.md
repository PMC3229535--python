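# arraybench

Benchmarking how **normalization, gene selection and machine learning
interact** when classifying patients from two-channel (two-colour spotted)
microarray data.

Classification studies on expression data usually report how well one
classifier separates two clinical classes. In practice the reported error
rate is the product of a whole pipeline — how the arrays were normalized,
which genes were kept, how many, and which learner was trained — and these
choices interact. `arraybench` implements that full factorial benchmark as
a reusable, tested library for methodologists who want to evaluate pipeline
combinations on their own (or synthetic) data:

* **Normalization (No 0–4)** — raw M-values; global or print-tip MA-loess;
  each with or without local background correction. M = log2(R/G),
  A = ½·log2(R·G); the loess fit of M on A is subtracted to remove
  intensity-dependent dye bias (per print-tip block for the local variants).
* **Preprocessing** — flagged spots become missing values; samples with
  ≥50% and genes with ≥30% missing values are removed simultaneously;
  remaining gaps are filled by iterative rank-*k* SVD imputation; duplicate
  gene IDs are averaged.
* **Gene selection** (training data only, inside the outer CV loop) —
  two-sided Welch t-test; a deterministic Relief variant in which every
  observation is visited exactly once; and a *paired-distance* ranker that
  scores gene pairs by the Euclidean distance √(Δᵢ² + Δⱼ²) between their two
  class-median points, with candidates restricted to the union of the 1000
  highest-variance and 1000 highest-|mean| genes. 21 gene counts from 2 to
  1000 are supported.
* **Classifiers** — eight configurations: CART trees (Gini / information
  gain) pruned by internal 10-fold CV; single-hidden-layer and no-hidden-
  layer neural networks (logistic units, weight decay 10⁻³, hidden size
  tuned over {2,…,5}); and nu-SVMs (ν = 0.2, unscaled inputs) with linear,
  degree-2/3 polynomial and radial-basis kernels, the RBF width tuned over
  a power-of-two grid on [2⁻¹⁴, 2¹⁴].
* **Evaluation** — patient-aware repeated double cross-validation
  (10 × 5-fold outer = 50 test sets; 10-fold inner CV for tuning). Error
  rates are reported raw and **adjusted**: divided by the random-assignment
  baseline 2p(1−p), so 1.0 means chance level. Class-label permutation
  tests quantify significance.
* **Comparison layer** — within each data set, methods (or method pairs)
  are compared by one-sided paired Wilcoxon signed-rank tests over all
  combinations matched on the remaining factors; counts of significantly
  better data sets form heatmaps (with a 7/5 rescaling for print-tip
  normalizations unavailable on single-block arrays), synergy matrices, and
  an OLS decomposition of error variance with pairwise interactions.

A seeded synthetic-data generator produces spot-level two-channel data sets
with known ground truth (planted differentially expressed genes, per-array
smooth dye-bias curves, print-tip offsets, additive background, flags,
duplicate spots, multi-sample patients), so every stage is testable without
any download.

## Worked example

```python
import numpy as np
import arraybench as ab
from arraybench.containers import MethodCombo

cfg = ab.SimConfig(n_genes=2000, n_samples=60, n_patients=60, n_diff=100,
                   effect_size=0.8, noise_sd=1.0, seed=1)
spots, meta = ab.generate_dataset(cfg)
matrix = ab.preprocess(ab.normalize_dataset(spots, meta, 3))  # global MA-loess

plan = ab.make_fold_plan(matrix.meta, repeats=10, outer_k=5, seed=2)
combo = MethodCombo(3, "ttest", 150, "SVM_Rb")
res = ab.run_double_cv(matrix, combo, plan, seed=3)
print(f"{combo}: error {res.mean_error:.4f} +/- {res.sd_error:.4f}, "
      f"adjusted {res.mean_adj_error:.4f}")

perm = ab.permutation_test(matrix, combo, n_perms=20, seed=4, repeats=2)
print(f"permutation null mean adjusted error: {np.mean(perm.null_values):.3f}")
print(f"observed value sits at the {perm.percentile:.0f}th percentile of the null")
```

prints

```
No3,ttest,150,SVM_Rb: error 0.0267 +/- 0.0489, adjusted 0.0533
permutation null mean adjusted error: 1.048
observed value sits at the 0th percentile of the null
```

The planted 100-gene signal (0.8 M-units against spot noise of SD 1) is
learned almost perfectly: the adjusted error 0.053 is far below the chance
level of 1.0, while the same pipeline on label-shuffled copies of the data
stays at chance (1.05) — the observed value falls below every permutation.

A thin CLI wraps the same functions: `arraybench simulate`, `arraybench
run --config cfg.yaml --dataset DIR --out results.csv`, `arraybench
permtest`, `arraybench compare --results results.csv --factor M`.

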