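"""Core domain containers shared across the pipeline.

All genomic coordinates are 0-based half-open internally; format readers in
:mod:`plastiscope.io` convert at the boundary.  For a minus-strand gene the
TSS coordinate is numerically larger than the TES, so ``tss > tes`` encodes
orientation together with ``strand``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneAnnotation",
    "GenomicInterval",
    "FoldChangeMatrix",
    "Pwm",
    "BindingProfile",
    "ValidationError",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class ValidationError(ValueError):
    """Raised when parsed data violate a semantic invariant."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to its representative transcript.

    ``tss`` and ``tes`` are 0-based positions; for strand ``-`` the TSS is
    the (numerically larger) end of the interval.  ``transcript_rank`` is an
    abundance rank used to pick the representative transcript (1 = most
    abundant).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    transcript_rank: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if self.tss == self.tes:
            raise ValidationError(f"zero-length gene {self.gene_id}")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValidationError(f"+ strand gene {self.gene_id} has tss >= tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValidationError(f"- strand gene {self.gene_id} has tss <= tes")

    @property
    def body(self) -> tuple[int, int]:
        """Gene body as a (start, end) half-open interval."""
        return (min(self.tss, self.tes), max(self.tss, self.tes))

    def promoter(self, window: tuple[int, int] = (-500, 500)) -> tuple[int, int]:
        """Promoter interval for a signed window relative to the TSS.

        ``window=(a, b)`` means from ``a`` bp (upstream if negative) to ``b``
        bp downstream in the direction of transcription.
        """
        a, b = window
        if not a < b:
            raise ValueError("window start must be less than window end")
        if self.strand == "+":
            return (self.tss + a, self.tss + b)
        return (self.tss - b, self.tss - a)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval, optionally carrying a peak p-value."""

    chrom: str
    start: int
    end: int
    score_p: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end} has start >= end"
            )
        if self.score_p is not None and not (0.0 < self.score_p <= 1.0):
            raise ValidationError(f"peak p-value {self.score_p} outside (0, 1]")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


class FoldChangeMatrix:
    """Gene x condition log2 fold changes with optional condition metadata.

    ``values`` is a float DataFrame (rows = genes, columns = conditions);
    missing entries are NaN.  Every retained row must have at least one
    observed value.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        condition_meta: pd.DataFrame | None = None,
    ) -> None:
        values = values.astype(float)
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene id(s): {dups}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate condition id(s): {dups}")
        all_missing = values.isna().all(axis=1)
        if all_missing.any():
            bad = values.index[all_missing].tolist()
            raise ValidationError(f"gene(s) with no observed fold change: {bad}")
        if condition_meta is not None:
            missing = values.columns.difference(condition_meta.index)
            if len(missing):
                raise ValidationError(
                    f"conditions without metadata: {missing.tolist()}"
                )
            condition_meta = condition_meta.loc[values.columns]
        self.values = values
        self.condition_meta = condition_meta

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def conditions(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_conditions(self, conditions) -> "FoldChangeMatrix":
        sub = self.values.loc[:, conditions]
        sub = sub.loc[~sub.isna().all(axis=1)]
        meta = None
        if self.condition_meta is not None:
            meta = self.condition_meta.loc[sub.columns]
        return FoldChangeMatrix(sub, meta)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FoldChangeMatrix({self.shape[0]} genes x {self.shape[1]} conditions)"


_BASES = "ACGT"


@dataclass
class Pwm:
    """Position probability matrix over {A, C, G, T} with a background."""

    motif_id: str
    matrix: np.ndarray  # shape (width, 4)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise FormatError(f"motif {self.motif_id}: matrix must be (width, 4)")
        if (self.matrix < 0).any() or (self.background < 0).any():
            raise FormatError(f"motif {self.motif_id}: negative probability")
        rows = self.matrix.sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-9:
            raise ValidationError(
                f"motif {self.motif_id}: position probabilities do not sum to 1"
            )
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValidationError(f"motif {self.motif_id}: background does not sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        rc = self.matrix[::-1, ::-1].copy()
        return Pwm(self.motif_id + "_rc", rc, self.background.copy())


@dataclass
class BindingProfile:
    """Genes bound by one factor (or carrying one mark) in one sample."""

    factor: str
    sample_id: str
    bound_genes: frozenset
    region_kind: str = "promoter"

    def __post_init__(self) -> None:
        if self.region_kind not in ("promoter", "gene_body"):
            raise ValueError(f"unknown region_kind {self.region_kind!r}")
        self.bound_genes = frozenset(self.bound_genes)
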