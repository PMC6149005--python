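"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle recomputes a quantity by direct enumeration or by the
definitional formula, deliberately sharing no code with the implementation
it checks.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from lncforge.core import GenomicInterval, TranscriptRecord

WC = {"AU", "UA", "GC", "CG"}
GU = {"GU", "UG"}
PAIRABLE = WC | GU


# ---------------------------------------------------------------------------
# positional pair classification, base by base
# ---------------------------------------------------------------------------


def _pos(iv: GenomicInterval) -> set:
    return set(range(iv.start, iv.end))


def _within_one_part(span: GenomicInterval, parts) -> bool:
    s = _pos(span)
    return any(s <= _pos(p) for p in parts)


def oracle_classify_pair(lnc: TranscriptRecord, mrna: TranscriptRecord) -> str:
    """Category via per-position set containment (slow, definitional)."""
    a, b = lnc.span, mrna.span
    if a.chrom != b.chrom or not (_pos(a) & _pos(b)):
        return "none"
    same = a.strand == b.strand
    if _within_one_part(a, mrna.exons):
        return "Lnc-CompleteIn-mRNAExon" if same else "Lnc-AntiCompleteIn-mRNAExon"
    if _within_one_part(a, mrna.introns):
        return "Lnc-CompleteIn-mRNAIntron" if same else "Lnc-AntiCompleteIn-mRNAIntron"
    if _within_one_part(b, lnc.exons):
        return "mRNA-CompleteIn-LncExon" if same else "mRNA-AntiCompleteIn-LncExon"
    if _within_one_part(b, lnc.introns):
        return "mRNA-CompleteIn-LncIntron" if same else "mRNA-AntiCompleteIn-LncIntron"
    return "Lnc-Overlap-mRNA" if same else "Lnc-Antioverlap-mRNA"


def random_transcript(rng, tid: str, lo: int = 0, hi: int = 3000,
                      biotype: str = "unknown") -> TranscriptRecord:
    """A random exon-structured transcript inside [lo, hi)."""
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(1, 4))
    pos = int(rng.integers(lo, hi - 600))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(30, 200))
        exons.append(GenomicInterval("chr1", pos, pos + length, strand))
        pos += length + int(rng.integers(20, 150))
    return TranscriptRecord.from_exons(tid, f"G{tid}", exons, biotype)


# ---------------------------------------------------------------------------
# decoy rescoring, per offset
# ---------------------------------------------------------------------------


def oracle_rescore_site(lnc_seq: str, mirna_seq: str, start: int
                        ) -> Optional[Tuple[int, int, float]]:
    """(mismatches, G·U pairs, expectation) for a site, by direct loop."""
    L = len(mirna_seq)
    window = lnc_seq[start : start + L]
    if len(window) < L:
        return None
    mism = gu = 0
    expectation = 0.0
    for k in range(L):
        p = L - k  # miRNA position (1-based, 5'->3') facing window index k
        duo = window[k] + mirna_seq[p - 1]
        if duo in WC:
            pen = 0.0
        elif duo in GU:
            pen = 0.5
            gu += 1
        else:
            pen = 1.0
            mism += 1
        if 2 <= p <= 13:
            pen *= 2
        expectation += pen
    return mism, gu, expectation


def oracle_scan_decoys(lnc_seq: str, mirna_seq: str,
                       expectation_max: float = 3.0,
                       mismatch_gu_max: int = 4) -> List[Tuple[int, int, int, float]]:
    out = []
    L = len(mirna_seq)
    for start in range(len(lnc_seq) - L + 1):
        mism, gu, exp = oracle_rescore_site(lnc_seq, mirna_seq, start)
        if exp < expectation_max and mism + gu <= mismatch_gu_max:
            out.append((start, mism, gu, exp))
    return out


# ---------------------------------------------------------------------------
# duplex energy, per offset
# ---------------------------------------------------------------------------


def oracle_duplex_energy(a: str, b: str, stack_table, pair_idx) -> float:
    """Best gapless hybrid by explicit enumeration of runs at all offsets."""
    best = 0.0
    na, nb = len(a), len(b)
    for i0 in range(na):
        for j0 in range(nb):
            if a[i0] + b[j0] not in PAIRABLE:
                continue
            if i0 > 0 and j0 + 1 < nb and a[i0 - 1] + b[j0 + 1] in PAIRABLE:
                continue  # not a run start
            run = [(i0, j0)]
            i, j = i0, j0
            while i + 1 < na and j - 1 >= 0 and a[i + 1] + b[j - 1] in PAIRABLE:
                i, j = i + 1, j - 1
                run.append((i, j))
            cur = 0.0
            for (p, q), (r, s) in zip(run, run[1:]):
                e = stack_table[pair_idx[a[p] + b[q]], pair_idx[a[r] + b[s]]]
                cur = min(cur, 0.0) + e
                best = min(best, cur)
    return best


# ---------------------------------------------------------------------------
# Benjamini–Hochberg, definitional step-up
# ---------------------------------------------------------------------------


def oracle_bh(p: np.ndarray) -> np.ndarray:
    """adj_(i) = min_{j >= i} (p_(j) * n / j), mapped back to input order."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(n)
    for rank_i in range(n):
        candidates = [
            p[order[rank_j]] * n / (rank_j + 1) for rank_j in range(rank_i, n)
        ]
        adj_sorted[rank_i] = min(1.0, min(candidates))
    out = np.empty(n)
    out[order] = adj_sorted
    return out
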