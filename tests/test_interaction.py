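"""Duplex energy, decoy-site scan, precursor matching, trans screening."""

import numpy as np
import pytest

from lncforge.core import ExpressionMatrix, SequenceStore, reverse_complement
from lncforge.expression import compute_fpkm
from lncforge.interaction import (
    STACK_TABLE,
    _PAIR_IDX,
    duplex_energy,
    match_precursors,
    scan_decoys,
    screen_trans_targets,
)
from lncforge.simulate import make_design

from oracles import oracle_duplex_energy, oracle_rescore_site, oracle_scan_decoys


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestDuplexEnergy:
    def test_no_complementarity_scores_zero(self):
        assert duplex_energy("A" * 25, "A" * 25) == 0.0

    def test_perfect_complement_equals_hand_sum(self):
        """Energy of s vs revcomp(s) is the sum of the len-1 stack terms."""
        s = "ACGUGGCUAGCUAGGCAUGC"
        rc = reverse_complement(s)
        expected = 0.0
        # pair i of the duplex is (s[i], rc[n-1-i]); the stacks accumulate 5'->3'
        n = len(s)
        for i in range(n - 1):
            p1 = _PAIR_IDX[s[i] + rc[n - 1 - i]]
            p2 = _PAIR_IDX[s[i + 1] + rc[n - 2 - i]]
            expected += STACK_TABLE[p1, p2]
        assert duplex_energy(s, rc) == pytest.approx(expected)
        assert expected < -30  # a 20-mer perfect duplex is strongly bound

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = _random_seq(rng, 40), _random_seq(rng, 25)
            assert duplex_energy(a, b) == duplex_energy(b, a)

    def test_never_positive_and_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(150):
            a = _random_seq(rng, int(rng.integers(2, 45)))
            b = _random_seq(rng, int(rng.integers(2, 45)))
            e = duplex_energy(a, b)
            assert e <= 0.0
            assert e == pytest.approx(
                oracle_duplex_energy(a, b, STACK_TABLE, _PAIR_IDX), abs=1e-9
            )

    def test_extension_monotonicity(self):
        """Growing a perfect complement never weakens the optimal energy."""
        rng = np.random.default_rng(3)
        s = _random_seq(rng, 30)
        prev = 0.0
        for k in range(2, 31):
            e = duplex_energy(s[:k], reverse_complement(s[:k]))
            assert e <= prev + 1e-12
            prev = e

    def test_invalid_alphabet(self):
        with pytest.raises(ValueError):
            duplex_energy("ACGX", "ACGU")


class TestScanDecoys:
    def test_perfect_complement_reported_with_zero_penalties(self):
        rng = np.random.default_rng(4)
        mir = _random_seq(rng, 21)
        host = _random_seq(rng, 200)
        site = reverse_complement(mir)
        lnc = host[:90] + site + host[90:]
        hits = scan_decoys(lnc, mir)
        exact = [h for h in hits if h.start == 90]
        assert len(exact) == 1
        h = exact[0]
        assert (h.mismatches, h.gu_pairs, h.expectation) == (0, 0, 0.0)
        assert h.end == 90 + 21

    def test_five_mismatches_rejected(self):
        rng = np.random.default_rng(5)
        mir = _random_seq(rng, 21)
        site = list(reverse_complement(mir))
        # corrupt five non-seed positions (window idx 0..4 face miRNA 17..21)
        for k in range(5):
            site[k] = {"A": "C", "C": "A", "G": "A", "U": "C"}[site[k]]
        lnc = "A" * 50 + "".join(site) + "A" * 50
        assert all(h.start != 50 for h in scan_decoys(lnc, mir))

    def test_hand_scored_non_seed_site(self):
        """2 mismatches + 1 G·U outside the seed: expectation 2.5, reported."""
        #      pos: 123456789012345678901  (miRNA 5'->3')
        mir = "ACGUACGUACGUACGUACGUA"
        site = list(reverse_complement(mir))
        # window index k faces miRNA position 21-k
        assert mir[14] == "G"  # position 15 (k=6); A pairs neither WC nor G·U
        site[6] = "A"
        assert mir[15] == "U"  # position 16 (k=5); C is a plain mismatch
        site[5] = "C"
        assert mir[19] == "U"  # position 20 (k=1); G gives a G·U wobble
        site[1] = "G"
        lnc = "C" * 40 + "".join(site) + "C" * 40
        hits = [h for h in scan_decoys(lnc, mir) if h.start == 40]
        assert len(hits) == 1
        assert hits[0].mismatches == 2 and hits[0].gu_pairs == 1
        assert hits[0].expectation == pytest.approx(2.5)

    def test_seed_doubling_pushes_expectation_over_threshold(self):
        """Two mismatches inside the seed region score 4 and are rejected."""
        mir = "ACGUACGUACGUACGUACGUA"
        site = list(reverse_complement(mir))
        # miRNA positions 5 and 8 lie in the seed-weighted region: k = 16, 13
        for k in (16, 13):
            p = 21 - k
            wc = {"A": "U", "U": "A", "G": "C", "C": "G"}[mir[p - 1]]
            site[k] = {"U": "C", "A": "C", "C": "A", "G": "A"}[wc]
        lnc = "C" * 30 + "".join(site) + "C" * 30
        assert all(h.start != 30 for h in scan_decoys(lnc, mir))

    def test_mirna_length_validated(self):
        with pytest.raises(ValueError, match="length"):
            scan_decoys("ACGU" * 30, "ACGUACGU")

    def test_mirna_longer_than_lncrna_yields_no_sites(self):
        assert scan_decoys("ACGUACGUAC", "ACGUACGUACGUACGUACGUA") == []

    def test_agreement_with_per_offset_oracle(self):
        rng = np.random.default_rng(6)
        mir = _random_seq(rng, 21)
        lnc = _random_seq(rng, 150) + reverse_complement(mir) + _random_seq(rng, 150)
        got = {(h.start, h.mismatches, h.gu_pairs, h.expectation)
               for h in scan_decoys(lnc, mir)}
        exp = set(oracle_scan_decoys(lnc, mir))
        assert got == exp and got


class TestMatchPrecursors:
    def _store(self, **seqs):
        s = SequenceStore()
        for k, v in seqs.items():
            s.add(k, v)
        return s

    def test_verbatim_insert_full_coverage(self):
        rng = np.random.default_rng(7)
        pre = _random_seq(rng, 120)
        lnc = _random_seq(rng, 100) + pre + _random_seq(rng, 100)
        (hit,) = match_precursors(lnc, self._store(p1=pre))
        assert hit.coverage == pytest.approx(1.0)
        assert hit.identity == pytest.approx(1.0)

    @pytest.mark.parametrize("frac,reported", [(0.95, True), (0.90, False),
                                               (0.85, False)])
    def test_coverage_threshold_strict(self, frac, reported):
        rng = np.random.default_rng(8)
        pre = _random_seq(rng, 100)
        k = round(frac * 100)
        # flank the truncated insert with bases that cannot extend the alignment
        tail_block = "".join(
            {"A": "C", "C": "A", "G": "U", "U": "G"}[b] for b in pre[k : k + 6]
        )
        lnc = _random_seq(rng, 80) + pre[:k] + tail_block + _random_seq(rng, 80)
        hits = match_precursors(lnc, self._store(p1=pre))
        assert bool(hits) is reported

    def test_empty_database_warns_and_returns_empty(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="lncforge.interaction"):
            assert match_precursors("ACGU" * 50, self._store()) == []
        assert "empty" in caplog.text


class TestScreenTrans:
    def _expr(self, values):
        import pandas as pd

        design = make_design(1)  # one replicate per group: 6 samples
        df = pd.DataFrame(values, index=[d.sample_id for d in design]).T
        return ExpressionMatrix(df, design, "fpkm")

    def test_correlation_threshold_inclusive(self):
        rng = np.random.default_rng(9)
        mrna = _random_seq(rng, 300)
        lnc = _random_seq(rng, 100) + reverse_complement(mrna[50:90]) \
            + _random_seq(rng, 100)
        seqs = SequenceStore()
        seqs.add("l", lnc)
        seqs.add("m", mrna)
        expr = self._expr({"l": [1, 2, 3, 4, 5, 6.0], "m": [2, 1, 4, 3, 6, 5.0]})
        from lncforge.expression import correlate_trends

        corr = correlate_trends([1, 2, 3, 4, 5, 6.0], [2, 1, 4, 3, 6, 5.0])
        # thresholds set exactly at the measured values: inclusive bounds pass
        hits = screen_trans_targets(
            "l", ["m"], seqs, expr, rho_min=corr.spearman, r_min=corr.pearson
        )
        assert len(hits) == 1
        # nudging either threshold above the measured value excludes the pair
        assert not screen_trans_targets(
            "l", ["m"], seqs, expr,
            rho_min=np.nextafter(corr.spearman, 2), r_min=corr.pearson,
        )

    def test_energy_passing_low_correlation_excluded(self):
        rng = np.random.default_rng(10)
        mrna = _random_seq(rng, 300)
        lnc = reverse_complement(mrna[50:90])
        seqs = SequenceStore()
        seqs.add("l", lnc)
        seqs.add("m", mrna)
        expr = self._expr({"l": [1, 2, 3, 4, 5, 6.0], "m": [6, 5, 4, 3, 2, 1.0]})
        assert screen_trans_targets("l", ["m"], seqs, expr) == []

    def test_missing_transcript_is_input_error(self):
        seqs = SequenceStore()
        seqs.add("l", "ACGU" * 30)
        expr = self._expr({"l": [1, 2, 3, 4, 5, 6.0]})
        with pytest.raises(ValueError, match="absent"):
            screen_trans_targets("l", ["m"], seqs, expr)

    def test_replicate_permutation_invariance(self, study):
        """Shuffling replicate columns within groups leaves the screen unchanged."""
        import pandas as pd

        fpkm = compute_fpkm(
            study.counts, {r.transcript_id: r.length for r in study.records}
        )
        pair = study.truth.corr_pairs[0]
        base = screen_trans_targets(
            pair["lnc_id"], [pair["mrna_id"]], study.transcript_seqs, fpkm
        )
        # reverse the replicate columns inside each (variety, stage) group
        values = fpkm.values.copy()
        for g in dict.fromkeys(d.group for d in fpkm.design):
            ids = fpkm.samples_in_group(g)
            values[ids] = fpkm.values[ids[::-1]].to_numpy()
        permuted = ExpressionMatrix(values, fpkm.design, "fpkm")
        after = screen_trans_targets(
            pair["lnc_id"], [pair["mrna_id"]], study.transcript_seqs, permuted
        )
        assert len(base) == len(after)
        for x, y in zip(base, after):
            assert (x.lnc_id, x.mrna_id) == (y.lnc_id, y.mrna_id)
            assert x.energy == y.energy
            assert x.pearson == pytest.approx(y.pearson)
            assert x.spearman == pytest.approx(y.spearman)


def test_planted_trans_pairs_recovered(study):
    fpkm = compute_fpkm(study.counts, {r.transcript_id: r.length for r in study.records})
    for p in study.truth.corr_pairs:
        reported = bool(
            screen_trans_targets(
                p["lnc_id"], [p["mrna_id"]], study.transcript_seqs, fpkm
            )
        )
        assert reported == p["expect_reported"], p["kind"]
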