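"""Sequence-level lncRNA function calls.

Three screens:

* ``duplex_energy`` — optimal gapless antiparallel RNA–RNA hybrid found by
  dynamic programming over a built-in nearest-neighbor stacking table
  (Watson–Crick and G·U stacks, kcal/mol at 37 °C).  A run of L stacked
  pairs scores the sum of its L−1 stack terms, so no duplex of at least
  two consecutive pairs means energy 0.
* ``scan_decoys`` — slides the reverse-complemented mature miRNA along a
  lncRNA and scores each offset with a seed-weighted penalty (mismatch 1,
  G·U 0.5, doubled at miRNA positions 2–13).  A site is a target-mimic
  candidate when the expectation is < 3 and mismatches + G·U pairs ≤ 4.
* ``match_precursors`` — local alignment (BLASTN-like scores) of known
  hairpin precursors against a lncRNA; a hit needs > 90 % precursor
  coverage (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numba
import numpy as np
from Bio import Align

from .core import ExpressionMatrix, SequenceStore, normalize_rna
from .expression import correlate_trends

logger = logging.getLogger(__name__)

DEFAULT_ENERGY_THRESHOLD = -30.0  # kcal/mol
DEFAULT_RHO_MIN = 0.6
DEFAULT_R_MIN = 0.6
DEFAULT_EXPECTATION_MAX = 3.0
DEFAULT_MISMATCH_GU_MAX = 4
DEFAULT_COVERAGE_MIN = 0.9
MIRNA_LENGTH_RANGE = (19, 24)
SEED_RANGE = (2, 13)  # miRNA positions (1-based, 5'->3') with doubled penalty

# ---------------------------------------------------------------------------
# nearest-neighbor stacking table
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
_PAIRS = ("AU", "UA", "GC", "CG", "GU", "UG")  # (top base, bottom base)
_PAIR_IDX = {p: i for i, p in enumerate(_PAIRS)}

# 5'->3' top dinucleotide over 3'<-5' bottom: stack of pair1 then pair2 is
# keyed (pair1, pair2).  Watson–Crick values follow the standard unified
# parameter set; G·U-containing stacks use representative values of the
# same magnitude class.  Rotational symmetry (reading the duplex from the
# other strand) is enforced programmatically.
_CANONICAL_STACKS = {
    # Watson–Crick / Watson–Crick
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CG", "UA"): -2.08,
    ("CG", "AU"): -2.11,
    ("GC", "UA"): -2.24,
    ("GC", "AU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GC", "GC"): -3.26,
    ("GC", "CG"): -3.42,
    # stacks containing one or two G·U wobbles
    ("AU", "GU"): -0.50,
    ("AU", "UG"): -0.60,
    ("UA", "GU"): -0.70,
    ("UA", "UG"): -0.60,
    ("CG", "GU"): -1.50,
    ("CG", "UG"): -1.40,
    ("GC", "GU"): -1.50,
    ("GC", "UG"): -1.60,
    ("GU", "GU"): -0.50,
    ("GU", "UG"): 0.50,
    ("UG", "GU"): -0.60,
}


def _rotate(pair: str) -> str:
    return pair[::-1]


def _build_stack_table() -> np.ndarray:
    table = np.full((6, 6), np.nan)
    for (p1, p2), e in _CANONICAL_STACKS.items():
        table[_PAIR_IDX[p1], _PAIR_IDX[p2]] = e
        table[_PAIR_IDX[_rotate(p2)], _PAIR_IDX[_rotate(p1)]] = e
    assert not np.isnan(table).any(), "stack table incomplete"
    return table


STACK_TABLE = _build_stack_table()

_PAIR_TYPE = np.full((5, 5), -1, dtype=np.int8)
for _p, _i in _PAIR_IDX.items():
    _PAIR_TYPE[_BASE_INDEX[_p[0]], _BASE_INDEX[_p[1]]] = _i

# 0 = Watson–Crick, 1 = G·U wobble, 2 = mismatch (N always mismatches)
_PAIR_CLASS = np.full((5, 5), 2, dtype=np.int8)
for _p in ("AU", "UA", "GC", "CG"):
    _PAIR_CLASS[_BASE_INDEX[_p[0]], _BASE_INDEX[_p[1]]] = 0
for _p in ("GU", "UG"):
    _PAIR_CLASS[_BASE_INDEX[_p[0]], _BASE_INDEX[_p[1]]] = 1


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        normalize_rna(seq).encode().translate(
            bytes.maketrans(b"ACGUN", bytes([0, 1, 2, 3, 4]))
        ),
        dtype=np.uint8,
    ).astype(np.intp)


# ---------------------------------------------------------------------------
# duplex energy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplexScore:
    lnc_id: str
    mrna_id: str
    energy: float  # kcal/mol, <= 0


@numba.njit(cache=True)
def _duplex_dp(ca, cb, pair_type, stack):  # pragma: no cover - compiled
    na, nb = ca.size, cb.size
    prev = np.empty(nb)
    cur = np.empty(nb)
    best = 0.0
    for i in range(na):
        for j in range(nb):
            t = pair_type[ca[i], cb[j]]
            if t < 0:
                cur[j] = np.inf
                continue
            v = 0.0
            if i > 0 and j + 1 < nb:
                tp = pair_type[ca[i - 1], cb[j + 1]]
                if tp >= 0:
                    e = prev[j + 1] + stack[tp, t]
                    if e < v:
                        v = e
            cur[j] = v
            if v < best:
                best = v
        prev, cur = cur, prev
    return best


def duplex_energy(a: str, b: str) -> float:
    """Free energy of the best gapless antiparallel hybrid of a and b.

    Returns 0.0 when no duplex of >= 2 consecutive (WC or G·U) pairs
    exists; otherwise the (negative) sum of stack terms of the best run.
    Dynamic programme over all antiparallel offsets: a run of L pairs
    scores the sum of its L-1 stack terms; single pairs score 0.
    """
    if len(b) < len(a) or (len(b) == len(a) and b < a):
        a, b = b, a  # canonical order keeps the result exactly symmetric
    ca, cb = _encode(a), _encode(b)
    if ca.size == 0 or cb.size == 0:
        raise ValueError("empty sequence")
    return float(_duplex_dp(ca, cb, _PAIR_TYPE, STACK_TABLE))


def score_duplex(lnc_id: str, mrna_id: str, seqs: SequenceStore) -> DuplexScore:
    return DuplexScore(lnc_id, mrna_id, duplex_energy(seqs[lnc_id], seqs[mrna_id]))


# ---------------------------------------------------------------------------
# miRNA decoy (target mimic) scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecoySite:
    lnc_id: str
    mirna_id: str
    start: int  # on the lncRNA, 0-based half-open
    end: int
    mismatches: int
    gu_pairs: int
    expectation: float


def decoy_penalties(mirna_length: int) -> np.ndarray:
    """Per-window-position weight: 2.0 inside the seed-weighted region.

    Window position k (5'->3' on the lncRNA) faces miRNA position
    ``mirna_length - k`` (1-based from the miRNA 5' end).
    """
    L = mirna_length
    positions = L - np.arange(L)  # miRNA position faced by window index k
    seed = (positions >= SEED_RANGE[0]) & (positions <= SEED_RANGE[1])
    return np.where(seed, 2.0, 1.0)


def scan_decoys(
    lnc_seq: str,
    mirna_seq: str,
    lnc_id: str = "lnc",
    mirna_id: str = "mirna",
    expectation_max: float = DEFAULT_EXPECTATION_MAX,
    mismatch_gu_max: int = DEFAULT_MISMATCH_GU_MAX,
) -> List[DecoySite]:
    """All miRNA-complementary sites on a lncRNA passing the decoy rule."""
    cm = _encode(mirna_seq)
    L = cm.size
    if not (MIRNA_LENGTH_RANGE[0] <= L <= MIRNA_LENGTH_RANGE[1]):
        raise ValueError(f"mature miRNA length {L} outside {MIRNA_LENGTH_RANGE}")
    cl = _encode(lnc_seq)
    if L > cl.size:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(cl, L)
    cls = _PAIR_CLASS[windows, cm[::-1][None, :]]  # antiparallel pairing
    weights = decoy_penalties(L)
    pen = np.array([0.0, 0.5, 1.0])[cls] * weights
    expectation = pen.sum(axis=1)
    mism = (cls == 2).sum(axis=1)
    gu = (cls == 1).sum(axis=1)
    keep = (expectation < expectation_max) & ((mism + gu) <= mismatch_gu_max)
    return [
        DecoySite(
            lnc_id,
            mirna_id,
            int(o),
            int(o) + L,
            int(mism[o]),
            int(gu[o]),
            float(expectation[o]),
        )
        for o in np.where(keep)[0]
    ]


def scan_decoys_all(
    lnc_seqs: SequenceStore,
    mirna_seqs: SequenceStore,
    expectation_max: float = DEFAULT_EXPECTATION_MAX,
    mismatch_gu_max: int = DEFAULT_MISMATCH_GU_MAX,
) -> List[DecoySite]:
    sites = []
    for lnc_id, lseq in lnc_seqs.items():
        for mir_id, mseq in mirna_seqs.items():
            sites.extend(
                scan_decoys(lseq, mseq, lnc_id, mir_id, expectation_max, mismatch_gu_max)
            )
    return sites


# ---------------------------------------------------------------------------
# miRNA precursor matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrecursorHit:
    lnc_id: str
    precursor_id: str
    coverage: float
    identity: float


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def match_precursors(
    lnc_seq: str,
    precursors: SequenceStore,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
    lnc_id: str = "lnc",
) -> List[PrecursorHit]:
    """Precursors locally aligning to the lncRNA with coverage > coverage_min."""
    if len(precursors) == 0:
        logger.warning("empty precursor database")
        return []
    aligner = _make_aligner()
    lnc = normalize_rna(lnc_seq)
    hits = []
    for pre_id, pre_seq in precursors.items():
        alignments = aligner.align(lnc, pre_seq)
        if len(alignments) == 0 or alignments.score <= 0:
            continue
        aln = alignments[0]
        t_blocks, q_blocks = aln.aligned
        covered = sum(int(q1 - q0) for q0, q1 in q_blocks)
        matches = sum(
            sum(x == y for x, y in zip(lnc[t0:t1], pre_seq[q0:q1]))
            for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks)
        )
        coverage = covered / len(pre_seq)
        identity = matches / covered if covered else 0.0
        if coverage > coverage_min:
            hits.append(PrecursorHit(lnc_id, pre_id, coverage, identity))
    return hits


# ---------------------------------------------------------------------------
# trans-target screening
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransTarget:
    lnc_id: str
    mrna_id: str
    energy: float
    spearman: float
    pearson: float


def screen_trans_targets(
    lnc_id: str,
    mrna_ids: Sequence[str],
    seqs: SequenceStore,
    expr: ExpressionMatrix,
    energy_threshold: float = DEFAULT_ENERGY_THRESHOLD,
    rho_min: float = DEFAULT_RHO_MIN,
    r_min: float = DEFAULT_R_MIN,
    energies: Optional[Dict[Tuple[str, str], float]] = None,
    use_group_means: bool = True,
) -> List[TransTarget]:
    """Trans targets of one lncRNA: binding energy plus dual co-expression.

    A candidate mRNA is reported iff energy <= energy_threshold AND
    Spearman >= rho_min AND Pearson >= r_min (all inclusive).  Correlations
    are computed across the six (variety, stage) group means by default.
    ``energies`` can carry externally computed hybridization energies
    (e.g. from a dedicated folding tool); missing pairs fall back to the
    built-in scorer.
    """
    if lnc_id not in expr.values.index:
        raise ValueError(f"{lnc_id} absent from expression matrix")
    if use_group_means:
        profiles = expr.group_means()
    else:
        profiles = expr.values
    x = profiles.loc[lnc_id].to_numpy(float)
    out = []
    for mrna_id in mrna_ids:
        if mrna_id not in expr.values.index:
            raise ValueError(f"{mrna_id} absent from expression matrix")
        if energies is not None and (lnc_id, mrna_id) in energies:
            energy = energies[(lnc_id, mrna_id)]
        else:
            energy = duplex_energy(seqs[lnc_id], seqs[mrna_id])
        if energy > energy_threshold:
            continue
        corr = correlate_trends(x, profiles.loc[mrna_id].to_numpy(float))
        if not corr.defined:
            continue
        if corr.spearman >= rho_min and corr.pearson >= r_min:
            out.append(TransTarget(lnc_id, mrna_id, energy, corr.spearman, corr.pearson))
    return out
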