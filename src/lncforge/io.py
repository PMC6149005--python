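"""Readers and writers for GTF, FASTA and the tabular inputs.

GTF parsing leans on :func:`gffutils.feature.feature_from_line` for field
and attribute handling; grouping into transcripts, coordinate conversion
(1-based inclusive → 0-based half-open) and line-numbered error reporting
are done here.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from pathlib import Path
from typing import Dict, List, Sequence

import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

from .core import (
    ExpressionMatrix,
    GenomicInterval,
    SampleDesign,
    SequenceStore,
    TranscriptRecord,
)


class GtfParseError(ValueError):
    pass


class SchemaError(ValueError):
    pass


def read_gtf(path) -> List[TranscriptRecord]:
    """Read exon features from a GTF file into TranscriptRecords.

    Exons are grouped per ``transcript_id``, sorted by start and converted
    to 0-based half-open coordinates; the span is the exon hull.
    """
    exons: "OrderedDict[str, list]" = OrderedDict()
    meta: Dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:
                raise GtfParseError(f"line {lineno}: malformed GTF line ({exc})")
            if feat.featuretype != "exon":
                continue
            if feat.strand not in ("+", "-"):
                raise GtfParseError(
                    f"line {lineno}: unknown strand symbol {feat.strand!r}"
                )
            start, end = feat.start - 1, feat.end  # to 0-based half-open
            if end <= start:
                raise GtfParseError(f"line {lineno}: end < start")
            try:
                tid = feat.attributes["transcript_id"][0]
                gid = feat.attributes["gene_id"][0]
            except KeyError as exc:
                raise GtfParseError(f"line {lineno}: missing attribute {exc}")
            biotype = feat.attributes.get("biotype", ["unknown"])[0]
            exons.setdefault(tid, []).append(
                GenomicInterval(feat.seqid, start, end, feat.strand)
            )
            meta[tid] = {"gene_id": gid, "biotype": biotype, "lineno": lineno}
    records = []
    for tid, ivs in exons.items():
        try:
            records.append(
                TranscriptRecord.from_exons(
                    tid, meta[tid]["gene_id"], ivs, meta[tid]["biotype"]
                )
            )
        except ValueError as exc:
            raise GtfParseError(
                f"near line {meta[tid]['lineno']}: invalid transcript {tid}: {exc}"
            )
    return records


def write_gtf(records: Sequence[TranscriptRecord], path) -> None:
    """Write one GTF exon line per exon; round-trips through read_gtf."""
    with open(path, "w") as fh:
        for rec in records:
            for e in rec.exons:
                attrs = (
                    f'gene_id "{rec.gene_id}"; transcript_id "{rec.transcript_id}"; '
                    f'biotype "{rec.biotype}";'
                )
                fh.write(
                    f"{e.chrom}\tlncforge\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )


def read_fasta(path) -> SequenceStore:
    store = SequenceStore()
    for rec in SeqIO.parse(str(path), "fasta"):
        store.add(rec.id, str(rec.seq))  # raises on duplicate id / bad alphabet
    return store


def write_fasta(store: SequenceStore, path) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in store.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_table(path, required_columns: Sequence[str]) -> pd.DataFrame:
    """Read a TSV with header and check the schema."""
    df = pd.read_csv(path, sep="\t")
    for col in required_columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


CODING_SCORE_COLUMNS = ("transcript_id", "cpc", "txcds", "cnci", "pfam_aligned")


def read_coding_scores(path) -> pd.DataFrame:
    return read_table(path, CODING_SCORE_COLUMNS)


def read_design(path) -> List[SampleDesign]:
    df = read_table(path, ("sample_id", "variety", "stage", "replicate"))
    return [
        SampleDesign(r.sample_id, r.variety, r.stage, int(r.replicate))
        for r in df.itertuples()
    ]


def read_expression(counts_path, design_path, units: str = "counts") -> ExpressionMatrix:
    design = read_design(design_path)
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    return ExpressionMatrix(df[[d.sample_id for d in design]], design, units)


def write_expression(matrix: ExpressionMatrix, counts_path, design_path=None) -> None:
    matrix.values.to_csv(counts_path, sep="\t", float_format="%.6g")
    if design_path is not None:
        pd.DataFrame(
            [
                {
                    "sample_id": d.sample_id,
                    "variety": d.variety,
                    "stage": d.stage,
                    "replicate": d.replicate,
                }
                for d in matrix.design
            ]
        ).to_csv(design_path, sep="\t", index=False)


def read_go_map(path) -> Dict[str, set]:
    """Term → set of gene ids."""
    df = read_table(path, ("term_id", "gene_id"))
    out: Dict[str, set] = {}
    for r in df.itertuples():
        out.setdefault(r.term_id, set()).add(r.gene_id)
    return out


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
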