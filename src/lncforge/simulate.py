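"""Synthetic study generator with planted ground truth.

Emulates the study design the pipeline expects — a small annotated
genome with lncRNAs and mRNAs, transcript/miRNA/precursor sequences, a
four-predictor coding-score table, and an 18-library count matrix
(2 varieties × 3 bud stages × 3 replicates) — and records every planted
feature in a :class:`TruthTable` so each downstream stage can be checked
against known truth:

* one lncRNA–mRNA pair fixture per positional category (×
  ``n_pairs_per_category``), geometrically constructed to satisfy exactly
  that category;
* lncRNAs just inside and just beyond the 20-kb cis window of an mRNA;
* miRNA decoy sites planted as perturbed reverse complements of mature
  miRNAs (positive controls satisfy the decoy rule, negative controls
  violate it in a recorded way);
* precursor subsequences inserted at controlled coverage fractions
  (1.00 / 0.95 positives, 0.85 negatives, one exact-0.90 boundary);
* trans-target pairs: a complementary insert plus a shared stage profile
  (positives), complementary insert with anticorrelated profiles, and
  correlated profiles with no complementarity (single-criterion failures);
* negative-binomial counts with planted fold changes in the NF variety.

Everything is deterministic given (config, seed); transcripts are placed
in disjoint 30-kb-separated slots so no unplanned pair geometry or cis
relationship arises.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    GenomicInterval,
    GROUP_ORDER,
    SampleDesign,
    SequenceStore,
    STAGES,
    TranscriptRecord,
    VARIETIES,
    reverse_complement,
)
from .geometry import PairCategory
from .interaction import (
    DEFAULT_ENERGY_THRESHOLD,
    DEFAULT_EXPECTATION_MAX,
    DEFAULT_MISMATCH_GU_MAX,
    decoy_penalties,
    duplex_energy,
    _PAIR_CLASS,
    _BASE_INDEX,
)

_BASES = "ACGU"
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
_GU_PARTNER = {"U": "G", "G": "U"}  # lncRNA base giving a G·U with this miRNA base
_SLOT_GAP = 30_000


class SizingError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_mrna: int = 150
    n_lnc: int = 150
    chrom_length: int = 25_000_000
    chrom_name: str = "chr1"
    mrna_length_range: Tuple[int, int] = (600, 2400)
    lnc_length_range: Tuple[int, int] = (250, 1200)
    mrna_exon_range: Tuple[int, int] = (2, 5)
    lnc_exon_range: Tuple[int, int] = (1, 2)
    n_short_lnc: int = 3  # planted below the 200-bp length filter
    n_pairs_per_category: int = 2
    n_cis_trios: int = 3
    cis_window: int = 20_000
    # miRNA decoys
    n_mirnas: int = 5
    mirna_length: int = 21
    n_decoy_sites: int = 20
    n_decoy_negatives: int = 20
    # precursors
    precursor_length: int = 120
    n_precursor_inserts: int = 8
    n_precursor_negatives: int = 4
    plant_boundary_precursor: bool = True
    # trans targets
    n_trans_pos: int = 4
    n_trans_anticorr: int = 3  # energy passes, correlation fails (negative r)
    n_trans_no_energy: int = 3  # correlation passes, no complementary region
    trans_insert_length: int = 30
    # expression
    n_replicates: int = 3
    n_de_genes: int = 60
    de_fold_change: float = 2.0
    nb_dispersion: float = 0.05
    library_size: float = 3_000_000.0
    # coding scores
    predictor_noise: float = 0.05
    predictor_noise_mode: str = "independent"  # or "one_dissenter"
    # GO map
    n_go_terms: int = 15
    go_term_size: Tuple[int, int] = (10, 30)

    def __post_init__(self) -> None:
        counts = [
            self.n_mrna, self.n_lnc, self.n_short_lnc, self.n_pairs_per_category,
            self.n_cis_trios, self.n_mirnas, self.n_decoy_sites,
            self.n_decoy_negatives, self.n_precursor_inserts,
            self.n_precursor_negatives, self.n_trans_pos, self.n_trans_anticorr,
            self.n_trans_no_energy, self.n_de_genes, self.n_go_terms,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not 0.0 <= self.predictor_noise <= 1.0:
            raise ValueError("predictor_noise must lie in [0, 1]")
        if self.de_fold_change < 1.0:
            raise ValueError("de_fold_change must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.predictor_noise_mode not in ("independent", "one_dissenter"):
            raise ValueError(f"unknown noise mode {self.predictor_noise_mode!r}")


@dataclass
class TruthTable:
    """Planted ground truth for every pipeline stage."""

    biotype: Dict[str, str] = field(default_factory=dict)
    pairs: List[dict] = field(default_factory=list)
    cis_pairs: List[dict] = field(default_factory=list)
    decoy_sites: List[dict] = field(default_factory=list)
    precursor_inserts: List[dict] = field(default_factory=list)
    de_genes: Dict[str, dict] = field(default_factory=dict)
    corr_pairs: List[dict] = field(default_factory=list)
    enriched_terms: List[str] = field(default_factory=list)
    roles: Dict[str, list] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "TruthTable":
        return TruthTable(**json.loads(text))


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def _split_exons(
    chrom: str, start: int, length: int, n_exons: int, strand: str, rng
) -> List[GenomicInterval]:
    n_exons = max(1, min(n_exons, length // 60))
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_exons - 1, replace=False)) \
        if n_exons > 1 else np.array([], dtype=int)
    sizes = np.diff(np.concatenate([[0], cuts, [length]]))
    sizes = np.maximum(sizes, 30)
    sizes = (sizes * length / sizes.sum()).astype(int)
    sizes[-1] = length - sizes[:-1].sum()
    if (sizes < 1).any():  # degenerate split: fall back to equal parts
        sizes = np.full(n_exons, length // n_exons)
        sizes[-1] = length - sizes[:-1].sum()
    exons, pos = [], start
    for i, s in enumerate(sizes):
        s = int(max(s, 1))
        exons.append(GenomicInterval(chrom, pos, pos + s, strand))
        pos += s
        if i < len(sizes) - 1:
            pos += int(rng.integers(80, 400))
    return exons


def _strands(rng, same: bool) -> Tuple[str, str]:
    m = "+" if rng.random() < 0.5 else "-"
    return (m if same else ("-" if m == "+" else "+")), m


def _pair_fixture(
    category: PairCategory, c: int, chrom: str, lnc_id: str, mrna_id: str, rng
) -> Tuple[TranscriptRecord, TranscriptRecord, int]:
    """Construct one lncRNA–mRNA pair satisfying exactly ``category``."""
    same = "Anti" not in category.value
    ls, ms = _strands(rng, same)
    j = int(rng.integers(0, 60))  # small jitter so fixtures are not identical

    def mrna_two_exon() -> TranscriptRecord:
        exons = [
            GenomicInterval(chrom, c, c + 1000, ms),
            GenomicInterval(chrom, c + 1600, c + 2600, ms),
        ]
        return TranscriptRecord.from_exons(mrna_id, f"G{mrna_id}", exons, "mRNA")

    cat = category.value
    if cat.endswith("mRNAExon") and cat.startswith("Lnc"):
        mrna = mrna_two_exon()
        L = int(rng.integers(250, 600))
        lnc = TranscriptRecord.from_exons(
            lnc_id, f"G{lnc_id}",
            [GenomicInterval(chrom, c + 100 + j, c + 100 + j + L, ls)], "lncRNA")
        return lnc, mrna, 2700
    if cat.endswith("mRNAIntron") and cat.startswith("Lnc"):
        mrna = mrna_two_exon()
        L = int(rng.integers(250, 400))
        lnc = TranscriptRecord.from_exons(
            lnc_id, f"G{lnc_id}",
            [GenomicInterval(chrom, c + 1050 + j, c + 1050 + j + L, ls)], "lncRNA")
        return lnc, mrna, 2700
    if "overlap" in cat.lower():
        mrna = mrna_two_exon()
        lnc = TranscriptRecord.from_exons(
            lnc_id, f"G{lnc_id}",
            [GenomicInterval(chrom, c + 2100 + j, c + 3100 + j, ls)], "lncRNA")
        return lnc, mrna, 3300
    if cat.endswith("LncExon"):
        lnc = TranscriptRecord.from_exons(
            lnc_id, f"G{lnc_id}",
            [GenomicInterval(chrom, c, c + 1500, ls),
             GenomicInterval(chrom, c + 2000, c + 2800, ls)], "lncRNA")
        mrna = TranscriptRecord.from_exons(
            mrna_id, f"G{mrna_id}",
            [GenomicInterval(chrom, c + 100 + j, c + 500 + j, ms),
             GenomicInterval(chrom, c + 700 + j, c + 1200 + j, ms)], "mRNA")
        return lnc, mrna, 3000
    if cat.endswith("LncIntron"):
        lnc = TranscriptRecord.from_exons(
            lnc_id, f"G{lnc_id}",
            [GenomicInterval(chrom, c, c + 400, ls),
             GenomicInterval(chrom, c + 2400, c + 2900, ls)], "lncRNA")
        mrna = TranscriptRecord.from_exons(
            mrna_id, f"G{mrna_id}",
            [GenomicInterval(chrom, c + 500 + j, c + 1100 + j, ms),
             GenomicInterval(chrom, c + 1400 + j, c + 2200 + j, ms)], "mRNA")
        return lnc, mrna, 3100
    raise ValueError(f"unknown category {category}")


_PLANTABLE_CATEGORIES = [c for c in PairCategory if c is not PairCategory.NONE]


def generate_annotation(config: GeneratorConfig) -> Tuple[List[TranscriptRecord], TruthTable]:
    """Place all transcripts on one chromosome; record planted geometry."""
    rng = np.random.default_rng([config.seed, 0])
    chrom = config.chrom_name
    truth = TruthTable()
    records: List[TranscriptRecord] = []
    cursor = 1000

    lnc_ids = [f"LNC{i:05d}" for i in range(1, config.n_lnc + 1)]
    mrna_ids = [f"MRNA{i:05d}" for i in range(1, config.n_mrna + 1)]
    need_lnc = 10 * config.n_pairs_per_category + 2 * config.n_cis_trios + config.n_short_lnc
    need_mrna = 10 * config.n_pairs_per_category + config.n_cis_trios
    if need_lnc > config.n_lnc or need_mrna > config.n_mrna:
        raise ValueError(
            f"n_lnc/n_mrna too small for planted features "
            f"(need >= {need_lnc} lncRNAs, {need_mrna} mRNAs)"
        )
    li = mi = 0

    def advance(span: int) -> None:
        nonlocal cursor
        cursor += span + _SLOT_GAP
        if cursor > config.chrom_length:
            raise SizingError(
                f"chrom_length {config.chrom_length} too small at position {cursor}"
            )

    # 1. positional pair fixtures
    for category in _PLANTABLE_CATEGORIES:
        for _ in range(config.n_pairs_per_category):
            lnc, mrna, span = _pair_fixture(
                category, cursor, chrom, lnc_ids[li], mrna_ids[mi], rng
            )
            li, mi = li + 1, mi + 1
            records.extend([lnc, mrna])
            truth.pairs.append(
                {"lnc_id": lnc.transcript_id, "mrna_id": mrna.transcript_id,
                 "category": category.value}
            )
            advance(span)

    # 2. cis trios: one mRNA, one lncRNA inside the window, one beyond
    for t in range(config.n_cis_trios):
        ms = "+" if rng.random() < 0.5 else "-"
        mrna = TranscriptRecord.from_exons(
            mrna_ids[mi], f"G{mrna_ids[mi]}",
            _split_exons(chrom, cursor, 1500, 2, ms, rng), "mRNA")
        mi += 1
        g_in = config.cis_window - 1 if t == 0 else int(rng.integers(1000, config.cis_window))
        g_out = config.cis_window + 1 if t == 0 else int(rng.integers(config.cis_window + 500, config.cis_window + 6000))
        placed = []
        for g, within in ((g_in, True), (g_out, False)):
            start = mrna.span.end + g
            L = int(rng.integers(*config.lnc_length_range))
            lnc = TranscriptRecord.from_exons(
                lnc_ids[li], f"G{lnc_ids[li]}",
                [GenomicInterval(chrom, start, start + L, "+" if rng.random() < 0.5 else "-")],
                "lncRNA")
            li += 1
            placed.append(lnc)
            d = g if mrna.span.strand == "+" else -g  # lnc lies 3' of the mRNA span
            truth.cis_pairs.append(
                {"lnc_id": lnc.transcript_id, "mrna_id": mrna.transcript_id,
                 "distance": d, "in_window": within}
            )
        records.append(mrna)
        records.extend(placed)
        advance(max(p.span.end for p in placed) - cursor)

    # 3. standalone transcripts (hosts for sequence-level plantings)
    standalone_lnc, standalone_mrna = [], []
    while li < config.n_lnc:
        short = (config.n_lnc - li) <= config.n_short_lnc
        L = int(rng.integers(150, 200)) if short \
            else int(rng.integers(*config.lnc_length_range))
        n_ex = int(rng.integers(config.lnc_exon_range[0], config.lnc_exon_range[1] + 1))
        rec = TranscriptRecord.from_exons(
            lnc_ids[li], f"G{lnc_ids[li]}",
            _split_exons(chrom, cursor, L, n_ex, "+" if rng.random() < 0.5 else "-", rng),
            "lncRNA")
        li += 1
        records.append(rec)
        (truth.roles.setdefault("short_lnc", []) if short else standalone_lnc).append(
            rec.transcript_id
        )
        advance(rec.span.end - cursor)
    while mi < config.n_mrna:
        L = int(rng.integers(*config.mrna_length_range))
        n_ex = int(rng.integers(config.mrna_exon_range[0], config.mrna_exon_range[1] + 1))
        rec = TranscriptRecord.from_exons(
            mrna_ids[mi], f"G{mrna_ids[mi]}",
            _split_exons(chrom, cursor, L, n_ex, "+" if rng.random() < 0.5 else "-", rng),
            "mRNA")
        mi += 1
        records.append(rec)
        standalone_mrna.append(rec.transcript_id)
        advance(rec.span.end - cursor)

    truth.roles["standalone_lnc"] = standalone_lnc
    truth.roles["standalone_mrna"] = standalone_mrna
    truth.roles.setdefault("short_lnc", [])
    for rec in records:
        truth.biotype[rec.transcript_id] = rec.biotype
    return records, truth


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _score_site(site: str, mirna: str) -> Tuple[int, int, float]:
    """Rescore a site with the decoy penalty scheme (mismatch/G·U counts)."""
    L = len(mirna)
    idx_site = np.array([_BASE_INDEX[b] for b in site])
    idx_mir = np.array([_BASE_INDEX[b] for b in mirna[::-1]])
    cls = _PAIR_CLASS[idx_site, idx_mir]
    pen = np.array([0.0, 0.5, 1.0])[cls] * decoy_penalties(L)
    return int((cls == 2).sum()), int((cls == 1).sum()), float(pen.sum())


def _mutated_site(mirna: str, n_mis: int, n_gu: int, seed_mis: int, rng) -> str:
    """Reverse complement of the miRNA with controlled perturbations.

    ``n_mis`` mismatches and ``n_gu`` G·U conversions at non-seed window
    positions, plus ``seed_mis`` mismatches inside the seed-weighted
    region.
    """
    L = len(mirna)
    site = list(reverse_complement(mirna))
    positions = L - np.arange(L)  # miRNA position faced by each window index
    nonseed = [k for k in range(L) if not (2 <= positions[k] <= 13)]
    seed = [k for k in range(L) if 2 <= positions[k] <= 13]
    gu_ok = [k for k in nonseed if mirna[positions[k] - 1] in _GU_PARTNER]
    if n_gu > len(gu_ok):  # prefer non-seed G·U; fall back to seed positions
        gu_ok += [k for k in seed if mirna[positions[k] - 1] in _GU_PARTNER]
    if n_gu > len(gu_ok):  # miRNA too A/C-rich: make up the count as mismatches
        n_mis += n_gu - len(gu_ok)
        n_gu = len(gu_ok)
    gu_pos = list(rng.choice(gu_ok, size=n_gu, replace=False)) if n_gu else []
    rest = [k for k in nonseed if k not in gu_pos]
    mis_pos = list(rng.choice(rest, size=n_mis, replace=False)) if n_mis else []
    seed_pos = list(rng.choice(seed, size=seed_mis, replace=False)) if seed_mis else []
    for k in gu_pos:
        site[k] = _GU_PARTNER[mirna[positions[k] - 1]]
    for k in mis_pos + seed_pos:
        m = mirna[positions[k] - 1]
        banned = {_WC[m], _GU_PARTNER.get(m, "")}
        site[k] = rng.choice([b for b in _BASES if b not in banned])
    return "".join(site)


def _insert(seq: str, insert: str, pos: int) -> str:
    return seq[:pos] + insert + seq[pos + len(insert):]


def generate_sequences(
    records: Sequence[TranscriptRecord],
    truth: TruthTable,
    config: GeneratorConfig,
) -> Tuple[SequenceStore, SequenceStore, SequenceStore]:
    """Transcript, mature-miRNA and precursor sequences with plantings."""
    rng = np.random.default_rng([config.seed, 1])
    seqs: Dict[str, str] = {
        r.transcript_id: _random_seq(rng, r.length) for r in records
    }

    mirnas = SequenceStore()
    for i in range(config.n_mirnas):
        mirnas.add(f"miR{i + 1:03d}", _random_seq(rng, config.mirna_length))

    n_pre_db = config.n_precursor_inserts + config.n_precursor_negatives \
        + int(config.plant_boundary_precursor) + 2  # +2 never planted
    precursors = SequenceStore()
    pre_ids = [f"pre-miR{i + 1:03d}" for i in range(n_pre_db)]
    for pid in pre_ids:
        precursors.add(pid, _random_seq(rng, config.precursor_length))

    hosts = list(truth.roles["standalone_lnc"])
    rng.shuffle(hosts)

    def take_hosts(n: int, min_len: int) -> List[str]:
        out = []
        while len(out) < n:
            if not hosts:
                raise SizingError("not enough standalone lncRNAs to host plantings")
            h = hosts.pop()
            if len(seqs[h]) >= min_len:
                out.append(h)
        return out

    # precursor inserts: prefix of the precursor, flanks guarded against
    # alignment extension into the host background
    plantings = []
    for i in range(config.n_precursor_inserts):
        cov = 1.0 if i % 2 == 0 else 0.95
        plantings.append((cov, True))
    for _ in range(config.n_precursor_negatives):
        plantings.append((0.85, False))
    if config.plant_boundary_precursor:
        plantings.append((0.90, False))
    P = config.precursor_length
    from .interaction import match_precursors

    for (cov, positive), host, pid in zip(
        plantings, take_hosts(len(plantings), P + 20), pre_ids
    ):
        k = round(cov * P)
        for _attempt in range(30):
            seq = _random_seq(rng, len(seqs[host]))
            pos = int(rng.integers(4, len(seq) - k - 8))
            seq = _insert(seq, precursors[pid][:k], pos)
            guarded = list(seq)
            for off in range(4):  # right flank must mismatch the precursor tail
                if k + off < P and pos + k + off < len(guarded):
                    avoid = precursors[pid][k + off]
                    guarded[pos + k + off] = rng.choice(
                        [b for b in _BASES if b != avoid]
                    )
            seq = "".join(guarded)
            # a control must sit on its intended side of the coverage rule:
            # gapped alignment into the random flank can otherwise inflate
            # the recovered coverage past the planted fraction
            one_pre = SequenceStore()
            one_pre.add(pid, precursors[pid])
            recovered = bool(match_precursors(seq, one_pre))
            if recovered == positive:
                break
        else:  # pragma: no cover
            raise SizingError(f"could not plant {pid} at coverage {cov}")
        seqs[host] = seq
        truth.precursor_inserts.append(
            {"lnc_id": host, "precursor_id": pid, "coverage": k / P,
             "positive": positive}
        )

    # miRNA decoy sites
    pos_patterns = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (2, 0, 0), (1, 1, 0), (2, 1, 0)]
    neg_patterns = [  # (n_mis, n_gu, seed_mis, reason)
        (5, 0, 0, "five_mismatches"),
        (0, 0, 2, "seed_expectation"),
        (0, 5, 0, "count_exceeded"),
    ]
    L = config.mirna_length
    mir_ids = list(mirnas)
    for i, host in enumerate(take_hosts(config.n_decoy_sites, L + 10)):
        mid = mir_ids[i % len(mir_ids)]
        n_mis, n_gu, seed_mis = pos_patterns[i % len(pos_patterns)]
        site = _mutated_site(mirnas[mid], n_mis, n_gu, seed_mis, rng)
        mis, gu, exp = _score_site(site, mirnas[mid])
        if not (exp < DEFAULT_EXPECTATION_MAX and mis + gu <= DEFAULT_MISMATCH_GU_MAX):
            # A/C-rich miRNA forced a seed-region G·U: use a cleaner pattern
            site = _mutated_site(mirnas[mid], min(n_mis, 2), 0, 0, rng)
            mis, gu, exp = _score_site(site, mirnas[mid])
        assert exp < DEFAULT_EXPECTATION_MAX and mis + gu <= DEFAULT_MISMATCH_GU_MAX
        pos = int(rng.integers(0, len(seqs[host]) - L))
        seqs[host] = _insert(seqs[host], site, pos)
        truth.decoy_sites.append(
            {"lnc_id": host, "mirna_id": mid, "start": pos, "end": pos + L,
             "mismatches": mis, "gu_pairs": gu, "expectation": exp,
             "positive": True, "reason": "planted_positive"}
        )
    for i, host in enumerate(take_hosts(config.n_decoy_negatives, L + 10)):
        mid = mir_ids[i % len(mir_ids)]
        n_mis, n_gu, seed_mis, reason = neg_patterns[i % len(neg_patterns)]
        site = _mutated_site(mirnas[mid], n_mis, n_gu, seed_mis, rng)
        mis, gu, exp = _score_site(site, mirnas[mid])
        assert exp >= DEFAULT_EXPECTATION_MAX or mis + gu > DEFAULT_MISMATCH_GU_MAX
        pos = int(rng.integers(0, len(seqs[host]) - L))
        seqs[host] = _insert(seqs[host], site, pos)
        truth.decoy_sites.append(
            {"lnc_id": host, "mirna_id": mid, "start": pos, "end": pos + L,
             "mismatches": mis, "gu_pairs": gu, "expectation": exp,
             "positive": False, "reason": reason}
        )

    # trans-target pairs
    m_hosts = list(truth.roles["standalone_mrna"])
    rng.shuffle(m_hosts)
    kinds = (
        [("trans_pos", True, 1)] * config.n_trans_pos
        + [("energy_pass_corr_fail", True, -1)] * config.n_trans_anticorr
        + [("corr_pass_energy_fail", False, 1)] * config.n_trans_no_energy
    )
    K = config.trans_insert_length
    for (kind, complementary, sign), lnc_host in zip(
        kinds, take_hosts(len(kinds), K + 20)
    ):
        mrna_host = m_hosts.pop()
        if complementary:
            u = int(rng.integers(0, len(seqs[mrna_host]) - K))
            frag = reverse_complement(seqs[mrna_host][u : u + K])
            pos = int(rng.integers(0, len(seqs[lnc_host]) - K))
            seqs[lnc_host] = _insert(seqs[lnc_host], frag, pos)
        else:
            # control must genuinely fail the energy criterion
            for _ in range(30):
                if duplex_energy(seqs[lnc_host], seqs[mrna_host]) > DEFAULT_ENERGY_THRESHOLD:
                    break
                seqs[lnc_host] = _random_seq(rng, len(seqs[lnc_host]))
            else:  # pragma: no cover
                raise SizingError("could not draw an energy-failing control")
        truth.corr_pairs.append(
            {"lnc_id": lnc_host, "mrna_id": mrna_host, "kind": kind,
             "sign": sign, "complementary": complementary,
             "expect_reported": kind == "trans_pos"}
        )

    store = SequenceStore()
    for r in records:  # preserve annotation order
        store.add(r.transcript_id, seqs[r.transcript_id])
    return store, mirnas, precursors


# ---------------------------------------------------------------------------
# coding scores and expression
# ---------------------------------------------------------------------------


def make_design(n_replicates: int = 3) -> List[SampleDesign]:
    return [
        SampleDesign(f"{v}-{s}-{r}", v, s, r)
        for v in VARIETIES
        for s in STAGES
        for r in range(1, n_replicates + 1)
    ]


def _draw_scores(rng, is_lnc_vote: np.ndarray) -> pd.DataFrame:
    n = is_lnc_vote.shape[0]
    cpc = np.where(is_lnc_vote[:, 0], rng.uniform(-3, -0.1, n), rng.uniform(0.1, 3, n))
    txcds = np.where(is_lnc_vote[:, 1], rng.uniform(100, 480, n), rng.uniform(520, 900, n))
    cnci = np.where(is_lnc_vote[:, 2], rng.uniform(-3, -0.1, n), rng.uniform(0.1, 3, n))
    pfam = ~is_lnc_vote[:, 3]
    return pd.DataFrame(
        {"cpc": np.round(cpc, 4), "txcds": np.round(txcds, 2),
         "cnci": np.round(cnci, 4), "pfam_aligned": pfam.astype(int)}
    )


#: Latent stage profile (multipliers over the six design groups in
#: canonical order) shared by planted co-expressed pairs.
_STAGE_PROFILE = np.array([0.3, 0.55, 1.0, 1.8, 3.3, 6.0])


def generate_scores_and_expression(
    records: Sequence[TranscriptRecord],
    truth: TruthTable,
    config: GeneratorConfig,
) -> Tuple[pd.DataFrame, ExpressionMatrix]:
    rng = np.random.default_rng([config.seed, 2])
    ids = [r.transcript_id for r in records]
    n = len(ids)
    is_lnc = np.array([truth.biotype[t] == "lncRNA" for t in ids])

    # predictor votes: truth with per-predictor dissent
    votes = np.repeat(is_lnc[:, None], 4, axis=1)
    if config.predictor_noise > 0:
        if config.predictor_noise_mode == "independent":
            flip = rng.random((n, 4)) < config.predictor_noise
        else:  # exactly one dissenting predictor per transcript
            flip = np.zeros((n, 4), bool)
            flip[np.arange(n), rng.integers(0, 4, n)] = True
        votes = votes ^ flip
    scores = _draw_scores(rng, votes)
    scores.insert(0, "transcript_id", ids)

    # planted DE genes: fold change applied in the NF variety, both directions
    eligible = [
        t for t in ids
        if t not in {p["lnc_id"] for p in truth.corr_pairs}
        and t not in {p["mrna_id"] for p in truth.corr_pairs}
    ]
    de_ids = list(rng.choice(eligible, size=min(config.n_de_genes, len(eligible)),
                             replace=False))
    directions = rng.choice([1, -1], size=len(de_ids))
    for t, d in zip(de_ids, directions):
        truth.de_genes[t] = {
            "fold_change": config.de_fold_change, "direction": int(d)
        }

    design = make_design(config.n_replicates)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    base *= config.library_size / base.sum()
    mult = np.ones((n, 6))
    idx = {t: i for i, t in enumerate(ids)}
    for t, info in truth.de_genes.items():
        fc = info["fold_change"] ** info["direction"]
        mult[idx[t], 3:] = fc  # NF groups occupy canonical positions 3..5
    for pair in truth.corr_pairs:
        prof = _STAGE_PROFILE / _STAGE_PROFILE.mean()
        mult[idx[pair["mrna_id"]], :] = prof
        mult[idx[pair["lnc_id"]], :] = prof if pair["sign"] > 0 else prof[::-1]

    group_of = {d.sample_id: f"{d.variety}-{d.stage}" for d in design}
    cols = {}
    for d in design:
        g = GROUP_ORDER.index(group_of[d.sample_id])
        mu = np.maximum(base * mult[:, g], 1e-8)
        if config.nb_dispersion > 0:
            r = 1.0 / config.nb_dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
        else:
            counts = rng.poisson(mu)
        cols[d.sample_id] = counts
    values = pd.DataFrame(cols, index=ids)
    return scores, ExpressionMatrix(values, design, "counts")


def generate_go_map(
    records: Sequence[TranscriptRecord],
    truth: TruthTable,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Synthetic term→gene map with one term enriched among DE genes."""
    rng = np.random.default_rng([config.seed, 3])
    ids = [r.transcript_id for r in records]
    rows = []
    de = [t for t in truth.de_genes if t in set(ids)]
    if de:
        members = list(rng.choice(de, size=min(15, len(de)), replace=False))
        members += list(rng.choice(ids, size=5, replace=False))
        for g in dict.fromkeys(members):
            rows.append({"term_id": "GO:ENRICHED", "gene_id": g})
        truth.enriched_terms.append("GO:ENRICHED")
    for i in range(config.n_go_terms):
        size = int(rng.integers(*config.go_term_size))
        for g in rng.choice(ids, size=size, replace=False):
            rows.append({"term_id": f"GO:{i + 1:07d}", "gene_id": g})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-call study bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    config: GeneratorConfig
    records: List[TranscriptRecord]
    truth: TruthTable
    transcript_seqs: SequenceStore
    mirna_seqs: SequenceStore
    precursor_seqs: SequenceStore
    scores: pd.DataFrame
    counts: ExpressionMatrix
    go_map: pd.DataFrame


def simulate_study(config: Optional[GeneratorConfig] = None) -> SimulatedStudy:
    config = config or GeneratorConfig()
    records, truth = generate_annotation(config)
    tseqs, mirnas, precursors = generate_sequences(records, truth, config)
    scores, counts = generate_scores_and_expression(records, truth, config)
    go_map = generate_go_map(records, truth, config)
    return SimulatedStudy(
        config, records, truth, tseqs, mirnas, precursors, scores, counts, go_map
    )


def write_study(study: SimulatedStudy, outdir) -> None:
    from pathlib import Path

    from .io import write_expression, write_fasta, write_gtf

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_gtf(study.records, out / "annotation.gtf")
    write_fasta(study.transcript_seqs, out / "transcripts.fa")
    write_fasta(study.mirna_seqs, out / "mirnas.fa")
    write_fasta(study.precursor_seqs, out / "precursors.fa")
    study.scores.to_csv(out / "coding_scores.tsv", sep="\t", index=False)
    write_expression(study.counts, out / "counts.tsv", out / "design.tsv")
    study.go_map.to_csv(out / "go_map.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(study.truth.to_json() + "\n")
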