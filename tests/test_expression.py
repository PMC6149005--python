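"""FPKM, NB Wald DE test, BH adjustment, hypergeometric enrichment, trends."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lncforge.core import ExpressionMatrix
from lncforge.expression import (
    DEFAULT_ALPHA,
    EnrichmentInput,
    bh_adjust,
    call_degs,
    compute_fpkm,
    correlate_trends,
    de_test,
    enrich,
    hypergeom_p,
)
from lncforge.simulate import make_design

from oracles import oracle_bh


def _matrix(values: dict, n_reps=3, units="counts"):
    design = make_design(n_reps)
    df = pd.DataFrame(values, index=[d.sample_id for d in design]).T
    return ExpressionMatrix(df, design, units)


class TestFpkm:
    def _simple(self, count):
        design = make_design(1)
        values = pd.DataFrame(
            {d.sample_id: [count, 10] for d in design}, index=["g1", "g2"]
        )
        # pad g2 so each library totals 1e6 fragments
        values.loc["g2"] = 1_000_000 - count
        return ExpressionMatrix(values, design, "counts")

    def test_definitional_value(self):
        # 10 fragments on a 1-kb transcript in a 1e6-fragment library -> FPKM 10
        m = self._simple(10)
        fpkm = compute_fpkm(m, {"g1": 1000, "g2": 500})
        assert fpkm.values.loc["g1"].iloc[0] == pytest.approx(10.0)

    def test_depth_invariance(self):
        m = self._simple(10)
        doubled = ExpressionMatrix(m.values * 2, m.design, "counts")
        f1 = compute_fpkm(m, {"g1": 1000, "g2": 500})
        f2 = compute_fpkm(doubled, {"g1": 1000, "g2": 500})
        assert np.allclose(f1.values, f2.values)

    def test_length_scaling_law(self):
        m = self._simple(250)
        f1 = compute_fpkm(m, {"g1": 1000, "g2": 500})
        f3 = compute_fpkm(m, {"g1": 3000, "g2": 1500})
        assert np.allclose(f1.values, f3.values * 3)

    def test_zero_count_and_zero_library(self):
        m = self._simple(0)
        assert compute_fpkm(m, {"g1": 1000, "g2": 500}).values.loc["g1"].iloc[0] == 0
        design = make_design(1)
        empty = ExpressionMatrix(
            pd.DataFrame({d.sample_id: [0] for d in design}, index=["g1"]),
            design, "counts",
        )
        with pytest.raises(ValueError, match="zero library"):
            compute_fpkm(empty, {"g1": 1000})


class TestDeTest:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(500, size=50)
        values = {f"g{i}": np.repeat(base[i], 18) for i in range(50)}
        m = _matrix(values)
        res = de_test(m, ("EF-Vb", "NF-Vb"))
        for r in res:
            assert r.fold_change == pytest.approx(1.0)
            assert r.p_value == pytest.approx(1.0)

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError, match="replicates"):
            de_test(_matrix({"g": np.arange(6) + 1.0}, n_reps=1), ("EF-Vb", "NF-Vb"))

    def test_planted_signal_ranks_above_null(self):
        """Fold-change-2 genes outrank nulls by p-value in >= 90% of pairings."""
        rng = np.random.default_rng(1)
        n, n_de = 400, 80
        disp = 0.05
        r = 1 / disp
        base = rng.lognormal(np.log(400), 0.8, n)
        rows = {}
        for i in range(n):
            mu = np.repeat(base[i], 18).astype(float)
            if i < n_de:
                mu[9:] *= 2.0  # NF samples occupy columns 9..17
            rows[f"g{i}"] = rng.negative_binomial(r, r / (r + mu))
        res = de_test(_matrix(rows), ("EF-Vb", "NF-Vb"))
        p = np.array([x.p_value for x in res])
        auc = (p[:n_de][:, None] < p[n_de:][None, :]).mean()
        assert auc >= 0.9

    def test_call_degs_thresholds(self):
        from lncforge.expression import DEResult

        res = [
            DEResult("up", ("A", "B"), 1.3, 1e-6),
            DEResult("down", ("A", "B"), 0.77, 1e-6),
            DEResult("weak_fc", ("A", "B"), 1.05, 1e-6),
            DEResult("weak_p", ("A", "B"), 5.0, 0.5),
        ]
        called = {r.transcript_id: r.is_de for r in call_degs(res)}
        assert called == {"up": True, "down": True, "weak_fc": False,
                          "weak_p": False}


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_unchanged(self):
        assert np.allclose(bh_adjust([0.2] * 7), 0.2)

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), oracle_bh(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestHypergeom:
    def test_empty_sum_is_one(self):
        assert hypergeom_p(EnrichmentInput(10, 5, 5, 0)) == 1.0

    def test_all_success_draw(self):
        # N=10, M=5, n=5, m=5: only 1 of C(10,5)=252 draws qualifies
        assert hypergeom_p(EnrichmentInput(10, 5, 5, 5)) == pytest.approx(
            1 / 252, abs=1e-15
        )

    def test_all_population_successes(self):
        # M = N forces every draw to be a success: the only attainable m is n
        assert hypergeom_p(EnrichmentInput(12, 12, 7, 7)) == pytest.approx(1.0)

    def test_matches_scipy_upper_tail(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            N = int(rng.integers(1, 200))
            M = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, n + M - N), min(n, M)
            m = int(rng.integers(lo, hi + 1))
            ours = hypergeom_p(EnrichmentInput(N, M, n, m))
            ref = sps.hypergeom.sf(m - 1, N, M, n)
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-13)

    def test_exact_fraction_enumeration_spot(self):
        inp = EnrichmentInput(40, 12, 15, 9)
        exact = sum(
            Fraction(comb(12, i) * comb(28, 15 - i), comb(40, 15))
            for i in range(9, 13)
        )
        assert hypergeom_p(inp) == pytest.approx(float(exact), abs=1e-14)

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            EnrichmentInput(10, 12, 5, 2)
        with pytest.raises(ValueError):
            EnrichmentInput(10, 5, 5, 6)

    def test_enrich_planted_term_is_top_hit(self, study):
        de = set(study.truth.de_genes)
        pop = {r.transcript_id for r in study.records}
        go = {}
        for row in study.go_map.itertuples():
            go.setdefault(row.term_id, set()).add(row.gene_id)
        results = enrich(de, pop, go)
        best = min(results, key=lambda e: e.p)
        assert best.term_id in study.truth.enriched_terms
        assert best.p < 1e-6


class TestTrendCorrelation:
    def test_linear_and_inverse(self):
        x = [1, 2, 3, 4, 5, 6.0]
        up = correlate_trends(x, [2 * v for v in x])
        assert up.pearson == pytest.approx(1.0) and up.spearman == pytest.approx(1.0)
        down = correlate_trends(x, [-v for v in x])
        assert down.pearson == pytest.approx(-1.0)
        assert down.spearman == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=6), rng.normal(size=6)
        got = correlate_trends(x, y)
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert got.pearson == pytest.approx(r)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rho = np.corrcoef(rx, ry)[0, 1]
        assert got.spearman == pytest.approx(rho)

    def test_zero_variance_flagged_not_zero(self):
        out = correlate_trends([1.0] * 6, [1, 2, 3, 4, 5, 6.0])
        assert not out.defined and np.isnan(out.pearson)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            correlate_trends([1, 2.0], [2, 1.0])
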