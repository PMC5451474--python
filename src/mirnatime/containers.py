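"""Tabular containers shared across the pipeline.

Count, TPM and FPKM matrices are thin wrappers around :class:`pandas.DataFrame`
with the axis conventions used throughout: rows are features (miRNAs or
genes), columns are libraries labelled ``"<breed>_<stage>"`` (e.g. ``LR_35E``).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "TpmMatrix", "FpkmMatrix", "parse_library_label"]


def parse_library_label(label: str) -> tuple[str, str]:
    """Split a library label ``"LR_35E"`` into ``("LR", "35E")``."""
    breed, _, stage = label.partition("_")
    if not breed or not stage:
        raise ValueError(f"library label {label!r} is not of the form BREED_STAGE")
    return breed, stage


def _check_axes(df: pd.DataFrame) -> None:
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate feature ids: {dup}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate library labels: {dup}")


@dataclass
class CountMatrix:
    """Raw tag counts per (miRNA, library) plus per-library totals.

    ``library_sizes`` holds the total number of mapped tags N_j per library;
    when not supplied it defaults to the column sums of ``counts`` (the counts
    then account for every mapped tag).  Supplied sizes must be at least the
    column sums: counted tags are a subset of mapped tags.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_axes(self.counts)
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        colsums = self.counts.sum(axis=0).astype(float)
        if self.library_sizes is None:
            self.library_sizes = colsums
        else:
            sizes = pd.Series(self.library_sizes, dtype=float)
            sizes = sizes.reindex(self.counts.columns)
            if sizes.isna().any():
                missing = sizes.index[sizes.isna()].tolist()
                raise ValueError(f"library_sizes missing for libraries: {missing}")
            low = sizes < colsums - 1e-6
            if low.any():
                bad = sizes.index[low].tolist()
                raise ValueError(
                    f"library_sizes smaller than column sums for: {bad} "
                    "(counted tags must be a subset of mapped tags)"
                )
            self.library_sizes = sizes

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_labels(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="mirna_id", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path, library_sizes: pd.Series | None = None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, library_sizes)


@dataclass
class TpmMatrix:
    """Tags-per-million normalized expression; same axes as the count matrix."""

    tpm: pd.DataFrame

    def __post_init__(self) -> None:
        _check_axes(self.tpm)
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")

    def to_tsv(self, path: str | Path) -> None:
        self.tpm.to_csv(path, sep="\t", index_label="mirna_id",
                        float_format="%.10g", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TpmMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class FpkmMatrix:
    """Gene expression (FPKM) over a stage time course, with its log2 view.

    ``log2_values`` is ``log2(fpkm + pseudocount)``; the pseudocount used is
    recorded so the transform is reproducible downstream.
    """

    fpkm: pd.DataFrame
    pseudocount: float = 1.0
    log2_values: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        _check_axes(self.fpkm)
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        self.log2_values = np.log2(self.fpkm + self.pseudocount)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.fpkm.index)

    def to_tsv(self, path: str | Path) -> None:
        self.fpkm.to_csv(path, sep="\t", index_label="gene_id",
                         float_format="%.10g", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path, pseudocount: float = 1.0) -> "FpkmMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0), pseudocount)
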