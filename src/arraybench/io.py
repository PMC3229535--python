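"""Plain-text I/O for spot tables, expression matrices and result tables.

Spot tables use a GenePix-like TSV dialect, one file per sample, with header
columns ``gene_id, block, R_fg, R_bg, G_fg, G_bg, flag``: ``gene_id`` maps
to the GPR "ID" column, ``block`` to "Block", the intensity columns to the
median foreground/background of the 635 nm (R) and 532 nm (G) channels, and
``flag`` collapses the GPR "Flags" column to flagged (1) / good (0).
Sample annotation travels in ``samples.tsv`` (sample_id, patient_id, class).

Expression matrices are genes x samples TSV with ``NA`` for missing values;
benchmark results use the CSV layout D, M, G, N, No, E, Esd, Eadj, Esdadj.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SampleMeta, SpotTable
from .evaluation import ComboResult

__all__ = ["write_spot_tables", "read_spot_tables", "write_matrix",
           "read_matrix", "results_frame", "write_results", "read_results"]

_SPOT_COLUMNS = ["gene_id", "block", "R_fg", "R_bg", "G_fg", "G_bg", "flag"]


def write_spot_tables(directory: str | Path, spots: list[SpotTable],
                      meta: list[SampleMeta]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s, m in zip(spots, meta):
        df = pd.DataFrame({
            "gene_id": s.gene_id, "block": s.block,
            "R_fg": s.R_fg, "R_bg": s.R_bg, "G_fg": s.G_fg, "G_bg": s.G_bg,
            "flag": s.flag.astype(int),
        })
        df.to_csv(directory / f"{m.sample_id}.tsv", sep="\t", index=False)
    pd.DataFrame({
        "sample_id": [m.sample_id for m in meta],
        "patient_id": [m.patient_id for m in meta],
        "class": [m.class_label for m in meta],
    }).to_csv(directory / "samples.tsv", sep="\t", index=False)


def read_spot_tables(directory: str | Path
                     ) -> tuple[list[SpotTable], list[SampleMeta]]:
    directory = Path(directory)
    ann = pd.read_csv(directory / "samples.tsv", sep="\t", dtype=str)
    meta = [SampleMeta(r.sample_id, r.patient_id, r["class"])
            for _, r in ann.iterrows()]
    spots = []
    for m in meta:
        df = pd.read_csv(directory / f"{m.sample_id}.tsv", sep="\t")
        missing = [c for c in _SPOT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{m.sample_id}.tsv lacks columns {missing}")
        spots.append(SpotTable(
            gene_id=df["gene_id"].to_numpy(dtype=object),
            block=df["block"].to_numpy(dtype=int),
            R_fg=df["R_fg"].to_numpy(dtype=float),
            R_bg=df["R_bg"].to_numpy(dtype=float),
            G_fg=df["G_fg"].to_numpy(dtype=float),
            G_bg=df["G_bg"].to_numpy(dtype=float),
            flag=df["flag"].to_numpy(dtype=bool),
        ))
    return spots, meta


def write_matrix(path: str | Path, matrix: ExpressionMatrix) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.gene_ids,
                      columns=matrix.sample_ids)
    df.to_csv(path, sep="\t", na_rep="NA", index_label="gene_id")
    meta_path = Path(path).with_suffix(".samples.tsv")
    pd.DataFrame({
        "sample_id": [m.sample_id for m in matrix.meta],
        "patient_id": [m.patient_id for m in matrix.meta],
        "class": [m.class_label for m in matrix.meta],
    }).to_csv(meta_path, sep="\t", index=False)


def read_matrix(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id", na_values=["NA"])
    meta_path = Path(path).with_suffix(".samples.tsv")
    if os.path.exists(meta_path):
        ann = pd.read_csv(meta_path, sep="\t", dtype=str)
        meta = [SampleMeta(r.sample_id, r.patient_id, r["class"])
                for _, r in ann.iterrows()]
    else:
        meta = [SampleMeta(c, c, "NA") for c in df.columns]
    return ExpressionMatrix(values=df.to_numpy(dtype=float),
                            gene_ids=[str(g) for g in df.index], meta=meta)


def results_frame(results: list[ComboResult]) -> pd.DataFrame:
    """Benchmark results as the canonical D, M, G, N, No, E, ... table."""
    return pd.DataFrame({
        "D": [r.dataset_id for r in results],
        "M": [r.combo.classifier for r in results],
        "G": [r.combo.selector for r in results],
        "N": [r.combo.n_genes for r in results],
        "No": [r.combo.normalization for r in results],
        "E": [r.mean_error for r in results],
        "Esd": [r.sd_error for r in results],
        "Eadj": [r.mean_adj_error for r in results],
        "Esdadj": [r.sd_adj_error for r in results],
    })


def write_results(path: str | Path, results: list[ComboResult]) -> None:
    results_frame(results).to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
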