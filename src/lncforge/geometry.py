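"""Positional lncRNA–mRNA classification and cis-window search.

Every overlapping lncRNA–mRNA pair falls into exactly one of ten
positional categories built from three axes: same chain vs antisense,
containment (within a single exon, within a single intron) vs partial
overlap, and which partner is contained.  Containment is evaluated on the
contained transcript's span (its exon hull) against a *single* exon or
intron of the host.  Checks are ordered: exon containment, then intron
containment, lncRNA-inside-mRNA before mRNA-inside-lncRNA, then partial
overlap; identical spans therefore resolve to a Lnc-…-In category.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Sequence

from intervaltree import IntervalTree

from .core import GenomicInterval, TranscriptRecord

DEFAULT_CIS_WINDOW = 20_000


class PairCategory(str, Enum):
    LNC_ANTI_IN_MRNA_EXON = "Lnc-AntiCompleteIn-mRNAExon"
    LNC_ANTI_IN_MRNA_INTRON = "Lnc-AntiCompleteIn-mRNAIntron"
    LNC_ANTI_OVERLAP_MRNA = "Lnc-Antioverlap-mRNA"
    LNC_IN_MRNA_EXON = "Lnc-CompleteIn-mRNAExon"
    LNC_IN_MRNA_INTRON = "Lnc-CompleteIn-mRNAIntron"
    LNC_OVERLAP_MRNA = "Lnc-Overlap-mRNA"
    MRNA_ANTI_IN_LNC_EXON = "mRNA-AntiCompleteIn-LncExon"
    MRNA_ANTI_IN_LNC_INTRON = "mRNA-AntiCompleteIn-LncIntron"
    MRNA_IN_LNC_EXON = "mRNA-CompleteIn-LncExon"
    MRNA_IN_LNC_INTRON = "mRNA-CompleteIn-LncIntron"
    NONE = "none"


@dataclass(frozen=True)
class PositionalPair:
    lnc_id: str
    mrna_id: str
    category: PairCategory


@dataclass(frozen=True)
class CisCandidate:
    lnc_id: str
    mrna_id: str
    distance: int  # signed, relative to the mRNA's strand; negative = lnc upstream


def _within_one(span: GenomicInterval, parts: Sequence[GenomicInterval]) -> bool:
    return any(p.contains(span) for p in parts)


def classify_pair(lnc: TranscriptRecord, mrna: TranscriptRecord) -> PairCategory:
    """Assign the positional category of one lncRNA–mRNA pair."""
    a, b = lnc.span, mrna.span
    if not a.overlaps(b):
        return PairCategory.NONE
    same = a.strand == b.strand

    if _within_one(a, mrna.exons):
        return (
            PairCategory.LNC_IN_MRNA_EXON if same else PairCategory.LNC_ANTI_IN_MRNA_EXON
        )
    if _within_one(a, mrna.introns):
        return (
            PairCategory.LNC_IN_MRNA_INTRON
            if same
            else PairCategory.LNC_ANTI_IN_MRNA_INTRON
        )
    if _within_one(b, lnc.exons):
        return (
            PairCategory.MRNA_IN_LNC_EXON if same else PairCategory.MRNA_ANTI_IN_LNC_EXON
        )
    if _within_one(b, lnc.introns):
        return (
            PairCategory.MRNA_IN_LNC_INTRON
            if same
            else PairCategory.MRNA_ANTI_IN_LNC_INTRON
        )
    return PairCategory.LNC_OVERLAP_MRNA if same else PairCategory.LNC_ANTI_OVERLAP_MRNA


def classify_all(
    lncs: Sequence[TranscriptRecord], mrnas: Sequence[TranscriptRecord]
) -> List[PositionalPair]:
    """Classify every span-overlapping lncRNA–mRNA pair (many-to-many)."""
    trees: Dict[str, IntervalTree] = {}
    by_id = {}
    for m in mrnas:
        trees.setdefault(m.span.chrom, IntervalTree()).addi(
            m.span.start, m.span.end, m.transcript_id
        )
        by_id[m.transcript_id] = m
    pairs = []
    for lnc in lncs:
        tree = trees.get(lnc.span.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(lnc.span.start, lnc.span.end), key=lambda h: h.data)
        for hit in hits:
            cat = classify_pair(lnc, by_id[hit.data])
            if cat is not PairCategory.NONE:
                pairs.append(PositionalPair(lnc.transcript_id, hit.data, cat))
    return pairs


def signed_distance(lnc: TranscriptRecord, mrna: TranscriptRecord) -> int:
    """Gap between spans, signed relative to the mRNA's orientation.

    0 when the spans overlap; negative when the lncRNA lies upstream of the
    mRNA (before its 5' end in transcription direction), positive when
    downstream.  Magnitude is the 0-based half-open gap length.
    """
    a, b = lnc.span, mrna.span
    if a.chrom != b.chrom:
        raise ValueError("transcripts on different chromosomes")
    if a.overlaps(b):
        return 0
    if a.end <= b.start:  # lnc to the left of the mRNA
        gap = b.start - a.end
        return -gap if b.strand == "+" else gap
    gap = a.start - b.end
    return gap if b.strand == "+" else -gap


def find_cis(
    lnc: TranscriptRecord,
    mrnas: Sequence[TranscriptRecord],
    window: int = DEFAULT_CIS_WINDOW,
    upstream_window: int | None = None,
) -> List[CisCandidate]:
    """mRNAs within the cis window of a lncRNA (overlap counts, distance 0).

    ``window`` bounds the downstream side; ``upstream_window`` the upstream
    side (defaults to ``window``, i.e. a symmetric ±window rule).
    """
    if upstream_window is None:
        upstream_window = window
    out = []
    for m in mrnas:
        if m.span.chrom != lnc.span.chrom:
            continue
        d = signed_distance(lnc, m)
        if (d == 0) or (d < 0 and -d <= upstream_window) or (0 < d <= window):
            out.append(CisCandidate(lnc.transcript_id, m.transcript_id, d))
    return out
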