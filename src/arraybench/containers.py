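"""Core in-memory containers shared across the pipeline.

A two-channel array experiment is represented at two levels:

* spot level -- one :class:`SpotTable` per hybridized array, holding the raw
  scanner quantities (foreground/background intensity per channel, print-tip
  block, flag) for every spot;
* matrix level -- one :class:`ExpressionMatrix` per data set, holding log2
  ratios (M-values) as a genes x samples array with ``NaN`` marking missing
  entries, plus per-sample annotation (patient, class).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "SpotTable",
    "ExpressionMatrix",
    "MethodCombo",
    "labels_of",
    "meta_frame",
]


@dataclass(frozen=True)
class SampleMeta:
    """Annotation of one hybridized array (= one sample)."""

    sample_id: str
    patient_id: str
    class_label: str


@dataclass
class SpotTable:
    """Raw spot-level quantities of one array.

    ``NaN`` in any intensity column marks a spot that has become missing
    (e.g. after background correction drove a channel nonpositive).
    """

    gene_id: np.ndarray          # str, one per spot; IDs may repeat (duplicates)
    block: np.ndarray            # int print-tip block, 1-based
    R_fg: np.ndarray
    R_bg: np.ndarray
    G_fg: np.ndarray
    G_bg: np.ndarray
    flag: np.ndarray             # bool, True = flagged by scanner/experimentalist

    def __post_init__(self) -> None:
        n = len(self.gene_id)
        for name in ("block", "R_fg", "R_bg", "G_fg", "G_bg", "flag"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} length mismatch")

    @property
    def n_spots(self) -> int:
        return len(self.gene_id)

    @property
    def n_blocks(self) -> int:
        return int(np.max(self.block))

    def copy(self) -> "SpotTable":
        return SpotTable(*(np.array(getattr(self, f), copy=True)
                           for f in ("gene_id", "block", "R_fg", "R_bg",
                                     "G_fg", "G_bg", "flag")))


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of M-values with missing entries as NaN.

    ``flags`` optionally carries the spot flags through from the raw data so
    that the preprocessing stage can convert them to missing values.
    """

    values: np.ndarray                 # float, shape (n_genes, n_samples)
    gene_ids: list[str]
    meta: list[SampleMeta]
    flags: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x samples)")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length must equal the row count")
        if len(self.meta) != self.values.shape[1]:
            raise ValueError("meta length must equal the column count")
        if self.flags is not None and self.flags.shape != self.values.shape:
            raise ValueError("flags must match the matrix shape")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.meta]

    def labels(self) -> np.ndarray:
        return labels_of(self.meta)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            gene_ids=list(self.gene_ids),
            meta=list(self.meta),
            flags=None if self.flags is None else self.flags.copy(),
        )

    def with_labels(self, labels: np.ndarray) -> "ExpressionMatrix":
        """Same matrix with per-sample class labels replaced (e.g. permuted)."""
        if len(labels) != self.n_samples:
            raise ValueError("one label per sample required")
        meta = [replace(m, class_label=str(l)) for m, l in zip(self.meta, labels)]
        return ExpressionMatrix(self.values, list(self.gene_ids), meta,
                                None if self.flags is None else self.flags)


@dataclass(frozen=True)
class MethodCombo:
    """One pipeline configuration: normalization id, gene selector, number of
    genes and classifier name."""

    normalization: int
    selector: str
    n_genes: int
    classifier: str

    def __str__(self) -> str:
        return f"No{self.normalization},{self.selector},{self.n_genes},{self.classifier}"

    @classmethod
    def parse(cls, text: str) -> "MethodCombo":
        """Parse the compact ``"No3,ttest,150,SVM_Rb"`` form."""
        no, sel, n, clf = (t.strip() for t in text.split(","))
        return cls(int(no.removeprefix("No")), sel, int(n), clf)


def labels_of(meta: list[SampleMeta]) -> np.ndarray:
    return np.array([m.class_label for m in meta], dtype=object)


def meta_frame(meta: list[SampleMeta]) -> pd.DataFrame:
    """Sample annotation as a DataFrame (sample_id, patient_id, class)."""
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "patient_id": [m.patient_id for m in meta],
            "class": [m.class_label for m in meta],
        }
    )
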