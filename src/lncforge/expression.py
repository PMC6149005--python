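"""Expression-level statistics.

FPKM computation, a per-gene negative-binomial Wald test for differential
expression between two (variety, stage) groups, Benjamini–Hochberg
adjustment, DEG calling at adjusted P < 0.01 with two-sided linear fold
change >= 1.2, stage-trend correlations, and the hypergeometric
enrichment test.

The DE test is deliberately plain: library sizes are normalized by
median-of-ratios, the per-gene NB dispersion is a method-of-moments
estimate pooled over the within-group residuals of *all* design groups
(never shared across genes), and the Wald statistic for the log ratio of
group means is referred to a t distribution with the dispersion
estimate's residual degrees of freedom.  No shrinkage or empirical-Bayes
moderation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix

DEFAULT_ALPHA = 0.01
DEFAULT_FC_MIN = 1.2
DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class DEResult:
    transcript_id: str
    contrast: Tuple[str, str]  # (group A, group B); fold change is B over A
    fold_change: float
    p_value: float
    adjusted_p: float = float("nan")
    is_de: bool = False


@dataclass(frozen=True)
class EnrichmentInput:
    N: int  # population size
    M: int  # population successes
    n: int  # sample size
    m: int  # sample successes

    def __post_init__(self) -> None:
        if not (0 <= self.M <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"invalid enrichment sizes {self}")
        if not (max(0, self.n + self.M - self.N) <= self.m <= min(self.n, self.M)):
            raise ValueError(f"sample successes m={self.m} out of range for {self}")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    input: EnrichmentInput
    p: float


@dataclass(frozen=True)
class TrendCorrelation:
    pearson: float
    spearman: float
    defined: bool


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------


def compute_fpkm(counts: ExpressionMatrix, lengths: Dict[str, int]) -> ExpressionMatrix:
    """FPKM[g,s] = counts[g,s] / (length_kb[g] * total_fragments[s] / 1e6)."""
    if counts.units != "counts":
        raise ValueError("compute_fpkm expects a counts matrix")
    missing = [t for t in counts.transcript_ids if t not in lengths]
    if missing:
        raise ValueError(f"missing lengths for {missing[:5]}...")
    totals = counts.values.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero library total in samples {bad}")
    len_kb = np.array([lengths[t] for t in counts.transcript_ids], float) / 1e3
    fpkm = counts.values.div(totals / 1e6, axis=1).div(len_kb, axis=0)
    return ExpressionMatrix(fpkm, counts.design, "fpkm")


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors (geometric-mean reference)."""
    logc = np.log(counts.replace(0, np.nan))
    log_ref = logc.mean(axis=1)
    usable = np.isfinite(log_ref)
    if not usable.any():
        raise ValueError("no gene observed in every sample; cannot normalize")
    ratios = logc.loc[usable].sub(log_ref[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def _mom_dispersion(
    norm: pd.DataFrame, groups: Sequence[List[str]]
) -> Tuple[np.ndarray, int]:
    """Per-gene NB dispersion and its residual degrees of freedom.

    Pooled over the within-group residuals of every design group with
    replicates, never shared across genes."""
    ss = np.zeros(len(norm))
    df = 0
    used = []
    for ids in groups:
        if len(ids) >= 2:
            sub = norm[ids].to_numpy(float)
            ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            df += len(ids) - 1
            used.extend(ids)
    if df < 1:
        raise ValueError("need at least one group with >= 2 replicates")
    var = ss / df
    mean = norm[used].to_numpy(float).mean(axis=1)
    mean = np.maximum(mean, 1e-8)
    return np.maximum((var - mean) / mean**2, DISPERSION_FLOOR), df


def de_test(
    counts: ExpressionMatrix,
    contrast: Tuple[str, str],
    pseudocount: float = PSEUDOCOUNT,
) -> List[DEResult]:
    """NB Wald test of group B vs group A for every transcript.

    ``contrast`` names two (variety, stage) groups, e.g. ("EF-Vb", "NF-Vb").
    """
    group_a, group_b = contrast
    ids_a = counts.samples_in_group(group_a)
    ids_b = counts.samples_in_group(group_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(f"contrast {contrast} needs >= 2 replicates per group")
    sf = size_factors(counts.values)
    norm = counts.values.div(sf, axis=1)

    all_groups = {}
    for d in counts.design:
        all_groups.setdefault(d.group, []).append(d.sample_id)
    disp, df = _mom_dispersion(norm, list(all_groups.values()))

    ma = norm[ids_a].mean(axis=1).to_numpy(float) + pseudocount
    mb = norm[ids_b].mean(axis=1).to_numpy(float) + pseudocount
    beta = np.log(mb) - np.log(ma)
    se2 = (1 / ma + disp) / len(ids_a) + (1 / mb + disp) / len(ids_b)
    z = beta / np.sqrt(se2)
    # t reference with the variance estimate's residual df: with few
    # replicates the plug-in dispersion makes a normal reference
    # anticonservative
    p = 2 * stats.t.sf(np.abs(z), df)
    fc = mb / ma
    return [
        DEResult(t, contrast, float(fc[i]), float(p[i]))
        for i, t in enumerate(counts.transcript_ids)
    ]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    results: Sequence[DEResult],
    alpha: float = DEFAULT_ALPHA,
    fc_min: float = DEFAULT_FC_MIN,
) -> List[DEResult]:
    """Attach BH-adjusted p-values and the DE call to Wald results.

    A transcript is differentially expressed iff adjusted P < alpha and
    max(FC, 1/FC) >= fc_min — the fold-change rule is two-sided on the
    linear scale, so 1.2-fold changes in either direction qualify.
    """
    adj = bh_adjust([r.p_value for r in results])
    out = []
    for r, a in zip(results, adj):
        effect = max(r.fold_change, 1 / r.fold_change)
        out.append(replace(r, adjusted_p=float(a), is_de=bool(a < alpha and effect >= fc_min)))
    return out


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------


def _log_comb(n: int, k) -> np.ndarray:
    k = np.asarray(k, float)
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def hypergeom_p(inp: EnrichmentInput) -> float:
    """Upper-tail hypergeometric probability P(X >= m).

    Equivalent to the complement-of-lower-sum form
    ``1 - sum_{i<m} C(M,i) C(N-M,n-i) / C(N,n)`` but summed directly over
    the upper tail in log space, which stays exact for tiny tails.
    """
    N, M, n, m = inp.N, inp.M, inp.n, inp.m
    if m == 0:
        return 1.0
    i = np.arange(m, min(n, M) + 1)
    log_terms = _log_comb(M, i) + _log_comb(N - M, n - i) - _log_comb(N, n)
    return float(min(1.0, np.exp(special.logsumexp(log_terms))))


def enrich(
    sample_genes: Set[str],
    population_genes: Set[str],
    go_map: Dict[str, Set[str]],
) -> List[EnrichmentResult]:
    """Hypergeometric term enrichment of a gene sample against a population."""
    pop = set(population_genes)
    samp = set(sample_genes) & pop
    results = []
    for term, genes in sorted(go_map.items()):
        members = genes & pop
        if not members:
            continue
        inp = EnrichmentInput(len(pop), len(members), len(samp), len(samp & members))
        results.append(EnrichmentResult(term, inp, hypergeom_p(inp)))
    return results


# ---------------------------------------------------------------------------
# stage-trend correlations
# ---------------------------------------------------------------------------


def correlate_trends(x: Sequence[float], y: Sequence[float]) -> TrendCorrelation:
    """Pearson and Spearman correlation of two expression series.

    Series are typically the six (variety, stage) group means in canonical
    order.  A zero-variance series makes both coefficients undefined; that
    is reported via ``defined=False`` rather than silently as 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("series must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TrendCorrelation(float("nan"), float("nan"), False)
    r = stats.pearsonr(x, y).statistic
    rho = stats.spearmanr(x, y).statistic
    return TrendCorrelation(float(r), float(rho), True)
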