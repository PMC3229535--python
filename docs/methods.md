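# Methods

## The benchmark procedure

One *combination* is a quadruple (normalization, gene selector, gene count,
classifier). Its performance on a data set is estimated by repeated double
cross-validation:

1. Normalization is applied per array, before any split. Each array is
   normalized independently of all others (a loess curve is fitted to that
   array's own M/A values), so no information crosses samples and
   normalizing ahead of the CV leaks nothing.
2. The outer 5-fold CV, repeated 10 times, yields 50 train/test splits.
   Fold construction is *patient-aware*: patients are shuffled and dealt
   round-robin to folds, all samples of a patient stay together, and
   distinct-patient counts per fold differ by at most one.
3. Inside each outer split, genes are ranked and selected on the training
   samples only. No second selection happens inside the inner loop; the
   inner 10-fold CV (stratified by class, seeded) is used solely to tune
   the one free parameter of the classifiers that have one (RBF width
   sigma, hidden-layer size) and to choose the decision trees' pruning
   level.
4. The error of one split is the plain misclassified fraction on the test
   fold. The *adjusted* error divides by the random-assignment baseline
   2p(1−p) computed from the full data set's class fractions; adjusted
   values below 1.0 beat chance. Because the adjustment is a constant
   rescaling, the mean/sd of adjusted errors equal the rescaled mean/sd of
   raw errors.

Class-label permutation tests shuffle labels at the *patient* level (all
samples of a patient keep a common label and the label multiset over
patients is preserved), rebuild the fold plan and rerun the double CV.

## Classifier configurations

| name | fixed settings | tuned |
|---|---|---|
| DT_Gini / DT_Information | CART, gini / entropy splitting | pruning level: cost-complexity path, 10-fold CV, minimum CV error, ties → simplest tree |
| NN_OneLayer | logistic units, decay 10⁻³, init U(±0.1), ≤100 L-BFGS iters | hidden size ∈ {2,3,4,5} |
| NN_NoLayer | as above, no hidden layer (direct input–output weights) | — |
| SVM_Linear / SVM_Poly2 / SVM_Poly3 | nu-SVC, ν=0.2, unscaled inputs; poly kernel (x·y + 1)^d | — |
| SVM_Rb | nu-SVC, ν=0.2, RBF kernel exp(−σ‖x−y‖²) | σ ∈ {2⁻¹⁴, 2⁻¹², …, 2¹⁴} |

Applicability limits: SVMs are not run with only two genes; NN_OneLayer is
capped at 150 genes and NN_NoLayer at 900.

The neural nets are implemented in-package as a single-hidden-layer
(optionally layer-free) logistic network so that the initialization range,
decay and iteration cap are exactly the stated contract and fits are
bit-reproducible under a seed. The objective is the mean cross-entropy plus
decay·‖w‖² over all weights; the classic R implementation this
configuration style comes from defaults to a least-squares fit criterion
instead — for a binary sigmoid output the two give practically identical
decision boundaries, and cross-entropy is the standard classification
likelihood. The grid step of 2² for sigma and the L-BFGS optimizer are
choices where only the interval, respectively "at most 100 iterations",
is fixed; both are configurable.

During sigma/size tuning, an inner-fold fit that fails (e.g. the ν
constraint becomes infeasible on a badly imbalanced inner fold) scores that
fold as error 1.0 rather than aborting; final fits propagate errors.

## Gene selection details

* **t-test**: Welch (unequal variances) two-sided p-values, ascending;
  genes with zero variance in both classes get p = 1. A pooled-variance
  option exists.
* **Relief** (deterministic variant): every observation is used exactly
  once, in index order. Nearest hit/miss are found by Euclidean distance
  over all genes; per-gene differences are scaled by the gene's observed
  range; a singleton-class observation contributes only its miss term.
  No weight threshold is applied.
* **Paired distance**: candidates = union of top-1000 by variance and
  top-1000 by |mean|, computed per training split (the selection lives
  inside the outer loop, so the cap is split-local). Δg is the difference
  of class medians; pairs rank by √(Δᵢ²+Δⱼ²) descending, ties by ascending
  indices. Ranked pairs are expanded to a gene list by walking pairs
  best-first and appending unseen genes, larger-|Δ| gene first when a pair
  straddles the requested count. The full pair ranking is computed by
  exhaustive vectorized enumeration over the candidate set (≤ 2000 genes →
  ≤ ~2·10⁶ pairs), which the unit tests hold against a brute-force oracle.
* Ties everywhere break by ascending gene index, making all three rankers
  deterministic.

## Preprocessing choices

"Less than 50% / 30% missing" is read strictly: a fraction exactly at the
threshold drops the sample/gene. Both fractions are computed once on the
input matrix and rows/columns are removed in one pass (simultaneous
filtering). SVD imputation uses k = 10 eigengenes (capped at min(dims)−1),
row-median initialization, relative Frobenius tolerance 10⁻², at most 100
iterations; observed entries are never altered. Choosing k near the data's
true rank matters: a much larger k over-parameterizes the completion and
the iteration stalls at its initialization. Duplicate averaging runs after
imputation, ignoring missing replicates.

## The synthetic-data generator

The generator emulates the structure the pipeline must cope with, bottom-up
from intensities so spot-level and matrix-level entry points agree:

* per-gene abundance on the A scale ~ U(7, 13) plus per-spot jitter;
* true M: ±effect_size/2 per class for the planted DE genes (random sign
  per gene), 0 otherwise, plus N(0, noise_sd) spot noise;
* dye bias: each array draws its own low-order polynomial curve in
  z = (A−10)/3 with coefficients scaled by `dye_bias_amplitude`, plus
  per-print-tip-block offsets when the layout has more than one block.
  Per-array curves are what make normalization matter: a bias curve shared
  by all arrays would cancel out of every between-class contrast;
* channels R = 2^(A+M/2), G = 2^(A−M/2); additive background contamination
  per channel (gamma-distributed around `background_level`), with the
  *measured* local background carrying multiplicative measurement noise
  (log-normal, sd 0.2) relative to the added contamination — so background
  correction is imperfect and weak spots can fall below background and
  become missing, as on real scanners;
* flags ~ Bernoulli(flag_rate); a `dup_rate` fraction of genes printed on
  two spots; patients get ≥1 samples each, classes assigned at the patient
  level.

Defaults (2000 genes, 60 single-sample patients, 50/50 classes, 100 DE
genes, effect 1.5, noise SD 1) describe a moderately hard two-class study.
What the generator does *not* emulate: spatial 2-D artifacts beyond block
offsets, one-channel designs, gene–gene correlation structure, and
class-correlated batch effects. Passing tests therefore show the pipeline's
internal correctness and calibration, not performance claims about any real
cancer data set.

## Calibration facts worth knowing

* The permutation null is the right calibration instrument: averaging the
  mean adjusted error over ≥50 label shuffles of one data set yields values
  centred close to 1.0 (the acceptance script measures ≈1.02 at its default
  scale).
* The mean adjusted error of a *single* fixed zero-effect data set is a
  much noisier statistic: across independent null data sets of n = 60 it
  spreads with SD ≈ 0.12 around ≈1.05 (the slight excess over 1.0 comes
  from the fixed class totals interacting with training-fold selection and
  fitting). Single-data-set chance-level checks should budget for that
  spread; only the permutation average tightens it.
* The normalization-benefit experiment (dye-bias amplitude 1.0) is run at
  effect 0.7 / noise SD 1.0: at substantially stronger signal both raw and
  normalized pipelines classify perfectly and the comparison is vacuous; at
  much weaker signal both sit at chance. The chosen point leaves raw-data
  errors mid-range so the benefit of removing the bias is measurable.

## Comparison layer

Within one data set, two levels of a factor (or of a factor pair) are
compared over all combinations matched on the remaining factors, by a
one-sided Wilcoxon signed-rank test (zero differences dropped; exact null
for small samples, continuity-corrected normal otherwise). One-sided tests
per direction mirror the directional "significantly better" counts; at most
one direction can be significant per data set. Individual-method heatmaps
use a Bonferroni threshold of 0.05 divided by the number of tests actually
performed in that heatmap; pair and synergy analyses use a fixed 0.05.
Counts involving the print-tip normalizations are rescaled by 7/5 (they are
unavailable on single-block layouts) and may therefore be non-integer.

Synergy of a pair (x, y): combinations containing both are tested against
the per-cell mean of combinations containing only x (and only y); per data
set, the better/worse single member is decided by the mean over matched
cells; significant wins over the better member count positively
(upper-right block), significant losses against the worse member count
negatively (lower-left block).

The regression decomposition fits OLS with categorical main effects (gene
count treated as categorical) and all pairwise interactions, reporting
adjusted R² and sequential ANOVA p-values against a 0.05/#terms threshold.

## Problem sizes used by the test suite

The suite exercises the full factorial machinery on reduced designs: double
CVs run at 2–10 repeats of 4–5 outer folds on 400–2000-gene data sets;
comparison-layer fixtures use a 4-point gene-count axis. These sizes were
chosen so the suite doubles as a usage reference while every statistical
check retains the power stated in its test.

## Known limitations

* Loess span (0.3), robustness iterations (3) and the minimum group size
  for print-tip fitting (10 spots) are community defaults, configurable;
  the smoother's curvature bias grows with span on strongly bent MA clouds.
* Inner CV folds are class-stratified but not patient-aware; with
  multi-sample patients the inner tuning estimate can be slightly
  optimistic (test-set estimates are unaffected).
* The Bonferroni denominator of the individual-method heatmap counts the
  tests of that heatmap only, not all heatmaps of a study.
* nu-SVC with ν = 0.2 requires each training class to hold at least 10% of
  the samples; heavily imbalanced designs should lower ν.
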