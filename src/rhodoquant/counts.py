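"""The per-sample, per-gene count table shared by the DNA and RNA paths.

A :class:`GeneCountTable` is a validated pandas DataFrame with one row
per (sample, gene): read or transcript counts plus the gene length and
class label needed for length-normalized coverage. The same schema
serves metagenome reads and metatranscriptome transcripts; only the
interpretation of ``count`` differs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidInputError, NotFoundError

#: Gene classes with dedicated semantics; anything else is "other".
GENE_CLASSES = ("PR", "recA", "rplB", "rpoB", "EF-Tu", "blh", "crtB", "crtY", "other")

REQUIRED_COLUMNS = ("sample_id", "gene_id", "gene_class", "gene_length", "count")
OPTIONAL_COLUMNS = ("otu_id", "color", "taxon")


@dataclass(frozen=True)
class GeneCountTable:
    """Validated gene count table.

    Invariants: positive gene lengths, non-negative integer counts,
    unique (sample_id, gene_id) pairs, known gene classes.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"count table missing required column {col!r}")
        if len(df) == 0:
            raise InvalidInputError("count table is empty")
        lengths = pd.to_numeric(df["gene_length"], errors="coerce")
        if lengths.isna().any() or (lengths <= 0).any():
            raise InvalidInputError("gene_length must be a positive number")
        counts = pd.to_numeric(df["count"], errors="coerce")
        if counts.isna().any() or (counts < 0).any():
            raise InvalidInputError("count must be a non-negative number")
        unknown = set(df["gene_class"].unique()) - set(GENE_CLASSES)
        if unknown:
            raise FormatError(f"unknown gene_class value(s): {sorted(unknown)}")
        dup = df.duplicated(subset=["sample_id", "gene_id"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["sample_id", "gene_id"]].tolist()
            raise InvalidInputError(f"duplicate (sample_id, gene_id) pair: {pair}")
        norm = df.copy()
        norm["gene_length"] = lengths.astype(float)
        norm["count"] = counts.astype(float)
        for col in OPTIONAL_COLUMNS:
            if col not in norm.columns:
                norm[col] = pd.NA
        object.__setattr__(self, "df", norm)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneCountTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    def sample(self, sample_id: str) -> pd.DataFrame:
        """Rows of one sample, with a ``coverage`` column (count/length)."""
        sub = self.df[self.df["sample_id"] == sample_id].copy()
        if len(sub) == 0:
            raise NotFoundError(f"sample {sample_id!r} not in count table")
        sub["coverage"] = sub["count"] / sub["gene_length"]
        return sub

    def scaled(self, factor: float) -> "GeneCountTable":
        """Same table with every count multiplied by ``factor`` (testing aid)."""
        if factor <= 0:
            raise InvalidInputError("scale factor must be positive")
        df = self.df.copy()
        df["count"] = df["count"] * factor
        return GeneCountTable(df)


def class_coverage(sample_df: pd.DataFrame, gene_class: str) -> float:
    """Summed length-normalized coverage of one gene class in a sample.

    Multiple assembled variants of a single-copy family all represent the
    same marker, so family coverage sums over them.
    """
    sel = sample_df[sample_df["gene_class"] == gene_class]
    return float(sel["coverage"].sum()) if len(sel) else 0.0


def gene_coverage(count: float, gene_length: float) -> float:
    """Length-normalized coverage of a single gene: count / gene_length."""
    if gene_length <= 0:
        raise InvalidInputError(f"gene_length must be positive, got {gene_length}")
    if count < 0:
        raise InvalidInputError(f"count must be non-negative, got {count}")
    return count / gene_length


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or value is pd.NA
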