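"""Core domain types shared by every pipeline stage.

Coordinates are 0-based half-open throughout the package; GTF I/O
(:mod:`lncforge.io`) converts to and from the 1-based inclusive convention
of the file format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Sequence

import numpy as np
import pandas as pd

VARIETIES = ("EF", "NF")
STAGES = ("Vb", "Tb", "Rb")
#: Canonical ordering of the six (variety, stage) groups used for
#: stage-trend correlations.
GROUP_ORDER = tuple(f"{v}-{s}" for v in VARIETIES for s in STAGES)

_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T→U; reject non-nucleotide characters."""
    s = seq.upper().replace("T", "U")
    if not set(s) <= set("ACGUN"):
        bad = sorted(set(s) - set("ACGUN"))
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    return s


def reverse_complement(seq: str) -> str:
    return normalize_rna(seq).translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """Span containment (ignores strand)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class TranscriptRecord:
    """An exon-structured transcript on one chromosome strand.

    ``exons`` are sorted, non-overlapping and lie within ``span``; introns
    are the gaps between consecutive exons, so a single-exon transcript has
    none.
    """

    transcript_id: str
    gene_id: str
    span: GenomicInterval
    exons: tuple
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.biotype not in ("mRNA", "lncRNA", "unknown"):
            raise ValueError(f"invalid biotype {self.biotype!r}")
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        for e in exons:
            if e.chrom != self.span.chrom or e.strand != self.span.strand:
                raise ValueError(
                    f"{self.transcript_id}: exon on different chrom/strand"
                )
            if not self.span.contains(e):
                raise ValueError(f"{self.transcript_id}: exon outside span")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def introns(self) -> List[GenomicInterval]:
        return [
            GenomicInterval(self.span.chrom, a.end, b.start, self.span.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if a.end < b.start
        ]

    @staticmethod
    def from_exons(
        transcript_id: str,
        gene_id: str,
        exons: Sequence[GenomicInterval],
        biotype: str = "unknown",
    ) -> "TranscriptRecord":
        """Build a record with the span computed as the exon hull."""
        exons = tuple(sorted(exons, key=lambda e: e.start))
        span = GenomicInterval(
            exons[0].chrom, exons[0].start, exons[-1].end, exons[0].strand
        )
        return TranscriptRecord(transcript_id, gene_id, span, exons, biotype)


class SequenceStore:
    """Mapping from sequence id to an RNA string (internally U, uppercase)."""

    def __init__(self) -> None:
        self._seqs: Dict[str, str] = {}

    def add(self, seq_id: str, seq: str) -> None:
        if seq_id in self._seqs:
            raise ValueError(f"duplicate sequence id {seq_id!r}")
        self._seqs[seq_id] = normalize_rna(seq)

    def __getitem__(self, seq_id: str) -> str:
        return self._seqs[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def items(self):
        return self._seqs.items()


@dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    variety: str
    stage: str
    replicate: int

    def __post_init__(self) -> None:
        if self.variety not in VARIETIES:
            raise ValueError(f"invalid variety {self.variety!r}")
        if self.stage not in STAGES:
            raise ValueError(f"invalid stage {self.stage!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    @property
    def group(self) -> str:
        return f"{self.variety}-{self.stage}"


class ExpressionMatrix:
    """Transcripts × samples expression values (counts or FPKM).

    Wraps a pandas DataFrame whose columns follow the sample design of the
    study: 2 varieties × 3 bud stages × replicates.
    """

    def __init__(self, values: pd.DataFrame, design: Sequence[SampleDesign], units: str):
        if units not in ("counts", "fpkm"):
            raise ValueError(f"invalid units {units!r}")
        design = list(design)
        keys = [(d.variety, d.stage, d.replicate) for d in design]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (variety, stage, replicate) in design")
        ids = [d.sample_id for d in design]
        if list(values.columns) != ids:
            raise ValueError("matrix columns do not match sample design")
        if values.index.has_duplicates:
            raise ValueError("duplicate transcript ids")
        if (values.to_numpy() < 0).any():
            raise ValueError("negative expression values")
        self.values = values
        self.design = design
        self.units = units

    @property
    def transcript_ids(self) -> List[str]:
        return list(self.values.index)

    def samples_in_group(self, group: str) -> List[str]:
        return [d.sample_id for d in self.design if d.group == group]

    def group_means(self) -> pd.DataFrame:
        """Mean per (variety, stage) group, columns in canonical order."""
        cols = {}
        for g in GROUP_ORDER:
            ids = self.samples_in_group(g)
            if ids:
                cols[g] = self.values[ids].mean(axis=1)
        return pd.DataFrame(cols)

    def subset(self, transcript_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(transcript_ids)], self.design, self.units)
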