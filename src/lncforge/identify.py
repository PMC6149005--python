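"""lncRNA / mRNA classification by length filter plus a 4-predictor vote.

A transcript is called a lncRNA when it is at least ``min_length`` bases
long and at least three of the four coding-potential predictors (CPC,
txCdspredict, CNCI, Pfam alignment) vote non-coding.  Scores exactly at a
threshold vote mRNA (the "≥ threshold = mRNA" convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Sequence

import pandas as pd

from .core import TranscriptRecord

logger = logging.getLogger(__name__)

CPC_THRESHOLD = 0.0
TXCDS_THRESHOLD = 500.0
CNCI_THRESHOLD = 0.0
MIN_LNC_VOTES = 3
DEFAULT_MIN_LENGTH = 200


@dataclass(frozen=True)
class CodingPotentialRecord:
    transcript_id: str
    cpc_score: float
    txcds_score: float
    cnci_score: float
    pfam_aligned: bool

    def __post_init__(self) -> None:
        for name in ("cpc_score", "txcds_score", "cnci_score"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{self.transcript_id}: non-finite {name}")


@dataclass(frozen=True)
class ClassificationResult:
    transcript_id: str
    label: str
    lnc_votes: int
    passed_length_filter: bool


def apply_length_filter(
    records: Sequence[TranscriptRecord], min_length: int = DEFAULT_MIN_LENGTH
) -> List[TranscriptRecord]:
    """Keep transcripts whose exonic length is >= min_length (inclusive)."""
    return [r for r in records if r.length >= min_length]


def predictor_votes(record: CodingPotentialRecord) -> Dict[str, str]:
    """Per-predictor labels; boundary scores vote mRNA."""

    def vote(is_lnc: bool) -> str:
        return "lncRNA" if is_lnc else "mRNA"

    return {
        "cpc": vote(record.cpc_score < CPC_THRESHOLD),
        "txcds": vote(record.txcds_score < TXCDS_THRESHOLD),
        "cnci": vote(record.cnci_score < CNCI_THRESHOLD),
        "pfam": vote(not record.pfam_aligned),
    }


def consensus_classify(
    record: CodingPotentialRecord,
    transcript: TranscriptRecord,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> ClassificationResult:
    """3-of-4 consensus vote combined with the length filter."""
    if record.transcript_id != transcript.transcript_id:
        raise ValueError(
            f"score/transcript id mismatch: {record.transcript_id} vs "
            f"{transcript.transcript_id}"
        )
    votes = predictor_votes(record)
    lnc_votes = sum(v == "lncRNA" for v in votes.values())
    passed = transcript.length >= min_length
    label = "lncRNA" if (lnc_votes >= MIN_LNC_VOTES and passed) else "mRNA"
    return ClassificationResult(record.transcript_id, label, lnc_votes, passed)


def classify_transcripts(
    transcripts: Sequence[TranscriptRecord],
    scores: pd.DataFrame,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> List[ClassificationResult]:
    """Classify every transcript that has a score row.

    Transcripts without a score row are excluded and logged — absence of a
    predictor run is not treated as a vote either way.
    """
    by_id = {}
    for r in scores.itertuples():
        by_id[r.transcript_id] = CodingPotentialRecord(
            r.transcript_id,
            float(r.cpc),
            float(r.txcds),
            float(r.cnci),
            bool(r.pfam_aligned),
        )
    results = []
    skipped = 0
    for t in transcripts:
        rec = by_id.get(t.transcript_id)
        if rec is None:
            skipped += 1
            continue
        results.append(consensus_classify(rec, t, min_length))
    if skipped:
        logger.warning("%d transcripts had no coding-potential scores; excluded", skipped)
    return results
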