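"""Synthetic two-channel microarray data with known ground truth.

The generator emulates the statistical structure a classification benchmark
on spotted two-colour arrays has to cope with:

* two patient classes, a configurable number of differentially expressed
  (DE) genes separated by a known shift of the log-ratio (M);
* intensity-dependent dye bias -- each array gets its own smooth low-order
  polynomial curve in A (average log intensity), which is exactly the
  artefact MA-loess normalization is designed to remove;
* per-print-tip-block offsets (absent when ``n_printtips == 1``,
  i.e. an Agilent-like layout);
* additive background intensity per channel, flagged spots, duplicate gene
  IDs and patients contributing several samples.

Intensities are generated bottom-up: a gene abundance on the A scale and a
true M-value yield the two channel signals ``R = 2**(A + M/2)`` and
``G = 2**(A - M/2)``; background is added on top of both foregrounds, so
local background correction can recover the signal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SampleMeta, SpotTable

__all__ = ["SimConfig", "generate_dataset", "generate_result_table",
           "GENE_COUNT_GRID_SMALL"]

CLASSES = ("classA", "classB")

#: reduced gene-count axis used by the factorial result-table fixtures
GENE_COUNT_GRID_SMALL = (2, 100, 500, 1000)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic data set.

    Defaults describe a 60-patient, 2000-gene two-class study with 100 DE
    genes shifted by 1.5 M-units against spot noise of SD 1 -- a moderately
    hard problem on which a reasonable classifier beats chance clearly but
    not trivially.
    """

    n_genes: int = 2000
    n_samples: int = 60
    n_patients: int = 60
    class_proportion: float = 0.5       # fraction of patients in classA
    n_diff: int = 100                   # number of DE genes
    effect_size: float = 1.5            # between-class difference in M units
    noise_sd: float = 1.0               # spot-level SD of M
    dye_bias_amplitude: float = 0.5     # scale of per-array smooth dye curves
    n_printtips: int = 16               # 1 => Agilent-like, no block structure
    background_level: float = 50.0      # mean additive background intensity
    flag_rate: float = 0.01
    dup_rate: float = 0.05              # fraction of genes printed twice
    seed: int = 0

    def validate(self) -> None:
        if self.n_diff > self.n_genes:
            raise ValueError("n_diff must not exceed n_genes")
        if self.n_patients > self.n_samples:
            raise ValueError("n_patients must not exceed n_samples")
        if not 0 < self.class_proportion < 1:
            raise ValueError("class_proportion must lie in (0,1)")
        for name in ("flag_rate", "dup_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0,1)")
        if self.n_printtips < 1 or self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0 or self.dye_bias_amplitude < 0 or self.background_level < 0:
            raise ValueError("scales must be nonnegative")


def _assign_patients(cfg: SimConfig, rng: np.random.Generator):
    """Patients with class labels; samples distributed over patients.

    Every patient receives at least one sample; surplus samples go to random
    patients, so some patients contribute several (same-class) samples.
    """
    n_a = int(round(cfg.class_proportion * cfg.n_patients))
    n_a = min(max(n_a, 1), cfg.n_patients - 1)
    pat_class = np.array([CLASSES[0]] * n_a + [CLASSES[1]] * (cfg.n_patients - n_a),
                         dtype=object)
    rng.shuffle(pat_class)
    owner = np.arange(cfg.n_patients)
    extra = rng.integers(0, cfg.n_patients, size=cfg.n_samples - cfg.n_patients)
    owner = np.concatenate([owner, extra])
    meta = [
        SampleMeta(sample_id=f"s{i:03d}", patient_id=f"p{owner[i]:03d}",
                   class_label=str(pat_class[owner[i]]))
        for i in range(cfg.n_samples)
    ]
    return meta


def generate_dataset(config: SimConfig, return_truth: bool = False):
    """Generate one synthetic data set.

    Returns ``(spot_tables, meta)`` -- one :class:`SpotTable` per sample plus
    the sample annotation.  With ``return_truth=True`` a third element is
    appended: a dict with the planted DE gene IDs and their shift signs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids = np.array([f"g{i:04d}" for i in range(config.n_genes)], dtype=object)
    base_A = rng.uniform(7.0, 13.0, size=config.n_genes)
    de_idx = rng.choice(config.n_genes, size=config.n_diff, replace=False)
    de_sign = rng.choice([-1.0, 1.0], size=config.n_diff)

    # class-conditional mean M per gene: +/- effect/2 for DE genes
    mu = {c: np.zeros(config.n_genes) for c in CLASSES}
    mu[CLASSES[0]][de_idx] = de_sign * config.effect_size / 2.0
    mu[CLASSES[1]][de_idx] = -de_sign * config.effect_size / 2.0

    meta = _assign_patients(config, rng)

    # spot layout shared by all arrays: every gene once, a subset twice
    n_dup = int(round(config.dup_rate * config.n_genes))
    dup_idx = rng.choice(config.n_genes, size=n_dup, replace=False) if n_dup else \
        np.empty(0, dtype=int)
    spot_gene = np.concatenate([np.arange(config.n_genes), dup_idx])
    n_spots = len(spot_gene)
    block = 1 + (np.arange(n_spots) * config.n_printtips) // n_spots

    spots: list[SpotTable] = []
    for m in meta:
        A = base_A[spot_gene] + rng.normal(0.0, 0.25, size=n_spots)
        M = mu[m.class_label][spot_gene] + rng.normal(0.0, config.noise_sd, size=n_spots)

        if config.dye_bias_amplitude > 0:
            # per-array smooth dye curve: quadratic in centred/scaled A
            z = (A - 10.0) / 3.0
            c = rng.normal(0.0, [0.3, 0.7, 0.7]) * config.dye_bias_amplitude
            M = M + c[0] + c[1] * z + c[2] * z * z
            if config.n_printtips > 1:
                offsets = rng.normal(0.0, 0.3 * config.dye_bias_amplitude,
                                     size=config.n_printtips)
                M = M + offsets[block - 1]

        R = np.exp2(A + M / 2.0)
        G = np.exp2(A - M / 2.0)
        if config.background_level > 0:
            # contamination added to the foreground vs. the locally *measured*
            # background differ by multiplicative measurement noise, so
            # correction is imperfect and weak spots can dip below background
            R_add = rng.gamma(4.0, config.background_level / 4.0, size=n_spots)
            G_add = rng.gamma(4.0, config.background_level / 4.0, size=n_spots)
            R_bg = R_add * np.exp(rng.normal(0.0, 0.2, size=n_spots))
            G_bg = G_add * np.exp(rng.normal(0.0, 0.2, size=n_spots))
        else:
            R_add = G_add = np.zeros(n_spots)
            R_bg = np.zeros(n_spots)
            G_bg = np.zeros(n_spots)
        flag = rng.random(n_spots) < config.flag_rate

        spots.append(SpotTable(
            gene_id=gene_ids[spot_gene].copy(),
            block=block.copy(),
            R_fg=R + R_add,
            R_bg=R_bg,
            G_fg=G + G_add,
            G_bg=G_bg,
            flag=flag,
        ))

    if return_truth:
        truth = {
            "de_genes": list(gene_ids[de_idx]),
            "de_index": de_idx.copy(),
            "de_sign": de_sign.copy(),
        }
        return spots, meta, truth
    return spots, meta


# ---------------------------------------------------------------------------
# factorial result-table fixtures for the comparison layer
# ---------------------------------------------------------------------------

_SELECTORS = ("ttest", "relief", "paired_distance")
_CLASSIFIERS = ("DT_Gini", "DT_Information", "NN_OneLayer", "NN_NoLayer",
                "SVM_Linear", "SVM_Poly2", "SVM_Poly3", "SVM_Rb")
_DOMINANT_CLASSIFIER = "SVM_Rb"
_SYNERGY_PAIR = {"M": "SVM_Rb", "G": "ttest"}


def _combo_applicable(clf: str, n: int) -> bool:
    if clf.startswith("SVM") and n == 2:
        return False
    if clf == "NN_OneLayer" and n > 150:
        return False
    if clf == "NN_NoLayer" and n > 900:
        return False
    return True


def generate_result_table(scheme: str, seed: int, n_datasets: int = 7,
                          gene_counts: tuple[int, ...] = GENE_COUNT_GRID_SMALL,
                          ) -> pd.DataFrame:
    """Full-factorial benchmark result table under a known scheme.

    ``scheme`` is one of:

    * ``"null"`` -- every combination draws its adjusted error i.i.d., so any
      method comparison is a true null;
    * ``"dominant-method"`` -- one classifier's errors are shifted down by
      0.1 everywhere, so it beats every other classifier in every data set;
    * ``"synergy-pair"`` -- only combinations containing *both* members of a
      designated (classifier, selector) pair are shifted down by 0.1.

    Columns follow the benchmark result layout: D (data set), M (classifier),
    G (selector), N (number of genes), No (normalization), Eadj.
    """
    if scheme not in ("null", "dominant-method", "synergy-pair"):
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)

    rows = []
    for d in range(n_datasets):
        for no, g, n, m in itertools.product(range(5), _SELECTORS, gene_counts,
                                             _CLASSIFIERS):
            if not _combo_applicable(m, n):
                continue
            e = rng.normal(0.35, 0.05)
            if scheme == "dominant-method" and m == _DOMINANT_CLASSIFIER:
                e -= 0.1
            if scheme == "synergy-pair" and m == _SYNERGY_PAIR["M"] \
                    and g == _SYNERGY_PAIR["G"]:
                e -= 0.1
            rows.append((f"D{d + 1}", m, g, n, no, max(e, 0.0)))
    return pd.DataFrame(rows, columns=["D", "M", "G", "N", "No", "Eadj"])
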