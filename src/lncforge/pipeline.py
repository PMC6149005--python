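"""End-to-end orchestration: identify → classify/cis → interaction → DE → enrich.

``run_pipeline`` reads all inputs named in a :class:`PipelineConfig`,
runs the stages in order, writes one TSV per stage plus a JSON manifest
with per-stage record counts, and is byte-deterministic for a fixed
(config, inputs) pair.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from .core import ExpressionMatrix
from .expression import call_degs, compute_fpkm, de_test, enrich
from .geometry import classify_all, find_cis
from .identify import apply_length_filter, classify_transcripts
from .interaction import match_precursors, scan_decoys_all, screen_trans_targets
from .io import (
    read_coding_scores,
    read_expression,
    read_fasta,
    read_go_map,
    read_gtf,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    gtf: str = "annotation.gtf"
    transcripts_fasta: str = "transcripts.fa"
    mirna_fasta: str = "mirnas.fa"
    precursor_fasta: str = "precursors.fa"
    scores_tsv: str = "coding_scores.tsv"
    counts_tsv: str = "counts.tsv"
    design_tsv: str = "design.tsv"
    go_map_tsv: str = "go_map.tsv"
    outdir: str = "results"
    # printed thresholds
    min_length: int = 200
    min_lnc_votes: int = 3
    cis_window: int = 20_000
    energy_threshold: float = -30.0
    rho_min: float = 0.6
    r_min: float = 0.6
    expectation_max: float = 3.0
    mismatch_gu_max: int = 4
    coverage_min: float = 0.9
    alpha: float = 0.01
    fc_min: float = 1.2
    seed: int = 0

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return PipelineConfig(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _require(path: str, stage: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise StageError(stage, f"missing input file: {path}")
    return p


def _corr_prefilter(
    profiles: pd.DataFrame, lnc_ids: List[str], mrna_ids: List[str], rho_min: float, r_min: float
) -> Dict[str, List[str]]:
    """Candidate mRNAs per lncRNA passing both correlation cutoffs.

    Cheap matrix pass used before the duplex-energy dynamic programme; the
    final screen re-applies all three criteria, so this only prunes.
    """

    def standardized(x):
        sd = x.std(axis=1, ddof=0)
        sd[sd == 0] = np.nan
        return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]

    vals = profiles.to_numpy(float)
    index = {t: i for i, t in enumerate(profiles.index)}
    li = [index[t] for t in lnc_ids]
    mi = [index[t] for t in mrna_ids]
    n = vals.shape[1]
    zs = standardized(vals)
    zr = standardized(sps.rankdata(vals, axis=1))
    r = (zs[li] @ zs[mi].T) / n
    rho = (zr[li] @ zr[mi].T) / n
    ok = (r >= r_min) & (rho >= rho_min)
    out: Dict[str, List[str]] = {}
    for a, lnc in enumerate(lnc_ids):
        out[lnc] = [mrna_ids[b] for b in np.where(ok[a])[0]]
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in (
                "min_length", "min_lnc_votes", "cis_window", "energy_threshold",
                "rho_min", "r_min", "expectation_max", "mismatch_gu_max",
                "coverage_min", "alpha", "fc_min",
            )
        },
        "counts": {},
    }

    # ---- identify -------------------------------------------------------
    stage = "identify"
    records = read_gtf(_require(config.gtf, stage))
    scores = read_coding_scores(_require(config.scores_tsv, stage))
    retained = apply_length_filter(records, config.min_length)
    results = classify_transcripts(retained, scores, config.min_length)
    by_id = {r.transcript_id: r for r in records}
    labels = {r.transcript_id: r.label for r in results}
    cls_df = pd.DataFrame(
        [
            {"transcript_id": r.transcript_id, "label": r.label,
             "lnc_votes": r.lnc_votes, "length": by_id[r.transcript_id].length}
            for r in results
        ]
    )
    cls_df.to_csv(out / "classification.tsv", sep="\t", index=False)
    lnc_recs = [by_id[t] for t, lab in labels.items() if lab == "lncRNA"]
    mrna_recs = [by_id[t] for t, lab in labels.items() if lab == "mRNA"]
    manifest["counts"][stage] = {
        "input_transcripts": len(records),
        "passed_length_filter": len(retained),
        "lncRNA": len(lnc_recs),
        "mRNA": len(mrna_recs),
    }

    # ---- positional classification & cis --------------------------------
    stage = "classify"
    pairs = classify_all(lnc_recs, mrna_recs)
    pd.DataFrame(
        [{"lnc_id": p.lnc_id, "mrna_id": p.mrna_id, "category": p.category.value}
         for p in pairs]
    ).to_csv(out / "pairs.tsv", sep="\t", index=False)
    cis_rows = []
    cis_of: Dict[str, set] = {}
    for lnc in lnc_recs:
        cands = find_cis(lnc, mrna_recs, config.cis_window)
        cis_of[lnc.transcript_id] = {c.mrna_id for c in cands}
        cis_rows.extend(
            {"lnc_id": c.lnc_id, "mrna_id": c.mrna_id, "distance": c.distance}
            for c in cands
        )
    pd.DataFrame(cis_rows).to_csv(out / "cis_candidates.tsv", sep="\t", index=False)
    manifest["counts"][stage] = {"pairs": len(pairs), "cis_candidates": len(cis_rows)}

    # ---- sequence-level interaction -------------------------------------
    stage = "interaction"
    seqs = read_fasta(_require(config.transcripts_fasta, stage))
    mirnas = read_fasta(_require(config.mirna_fasta, stage))
    precursors = read_fasta(_require(config.precursor_fasta, stage))
    lnc_ids = sorted(r.transcript_id for r in lnc_recs)
    mrna_ids = sorted(r.transcript_id for r in mrna_recs)

    from .core import SequenceStore

    lnc_store = SequenceStore()
    for t in lnc_ids:
        if t not in seqs:
            raise StageError(stage, f"transcript {t} missing from FASTA")
        lnc_store.add(t, seqs[t])
    decoys = scan_decoys_all(
        lnc_store, mirnas, config.expectation_max, config.mismatch_gu_max
    )
    pd.DataFrame(
        [{"lnc_id": d.lnc_id, "mirna_id": d.mirna_id, "start": d.start,
          "end": d.end, "mismatches": d.mismatches, "gu_pairs": d.gu_pairs,
          "expectation": d.expectation}
         for d in decoys]
    ).to_csv(out / "decoy_sites.tsv", sep="\t", index=False, float_format="%.3f")

    precursor_hits = []
    for t in lnc_ids:
        precursor_hits.extend(
            match_precursors(seqs[t], precursors, config.coverage_min, lnc_id=t)
        )
    pd.DataFrame(
        [{"lnc_id": h.lnc_id, "precursor_id": h.precursor_id,
          "coverage": h.coverage, "identity": h.identity}
         for h in precursor_hits]
    ).to_csv(out / "precursor_hits.tsv", sep="\t", index=False, float_format="%.4f")

    stage = "trans_targets"
    counts = read_expression(
        _require(config.counts_tsv, stage), _require(config.design_tsv, stage)
    )
    lengths = {r.transcript_id: r.length for r in records}
    fpkm = compute_fpkm(counts, lengths)
    profiles = fpkm.group_means()
    candidates = _corr_prefilter(
        profiles, lnc_ids, mrna_ids, config.rho_min, config.r_min
    )
    trans = []
    for lnc in lnc_ids:
        cands = [m for m in candidates[lnc] if m not in cis_of.get(lnc, set())]
        if cands:
            trans.extend(
                screen_trans_targets(
                    lnc, cands, seqs, fpkm,
                    config.energy_threshold, config.rho_min, config.r_min,
                )
            )
    pd.DataFrame(
        [{"lnc_id": t.lnc_id, "mrna_id": t.mrna_id, "energy": t.energy,
          "spearman": t.spearman, "pearson": t.pearson}
         for t in trans]
    ).to_csv(out / "trans_targets.tsv", sep="\t", index=False, float_format="%.4f")
    manifest["counts"]["interaction"] = {
        "decoy_sites": len(decoys),
        "precursor_hits": len(precursor_hits),
        "trans_targets": len(trans),
    }

    # ---- differential expression ----------------------------------------
    stage = "de"
    tested = [t for t in counts.transcript_ids if t in labels]
    counts = counts.subset(tested)
    de_rows = []
    de_ids: Dict[str, set] = {}
    for s in ("Vb", "Tb", "Rb"):
        contrast = (f"EF-{s}", f"NF-{s}")
        called = call_degs(de_test(counts, contrast), config.alpha, config.fc_min)
        de_ids[s] = {r.transcript_id for r in called if r.is_de}
        de_rows.extend(
            {"transcript_id": r.transcript_id, "contrast": f"NF-{s}.vs.EF-{s}",
             "fold_change": r.fold_change, "p_value": r.p_value,
             "adjusted_p": r.adjusted_p, "is_de": int(r.is_de),
             "label": labels.get(r.transcript_id, "unknown")}
            for r in called
        )
    de_df = pd.DataFrame(de_rows)
    de_df.to_csv(out / "de_results.tsv", sep="\t", index=False, float_format="%.6g")
    all_de = set().union(*de_ids.values())
    manifest["counts"][stage] = {
        "DEGs": len([t for t in all_de if labels.get(t) == "mRNA"]),
        "DELs": len([t for t in all_de if labels.get(t) == "lncRNA"]),
        "per_contrast": {s: len(v) for s, v in sorted(de_ids.items())},
    }

    # ---- enrichment ------------------------------------------------------
    stage = "enrich"
    go_map = read_go_map(_require(config.go_map_tsv, stage))
    population = set(labels)
    enr = enrich(all_de, population, go_map)
    from .expression import bh_adjust

    adj = bh_adjust([e.p for e in enr]) if enr else []
    pd.DataFrame(
        [{"term_id": e.term_id, "N": e.input.N, "M": e.input.M, "n": e.input.n,
          "m": e.input.m, "p": e.p, "adjusted_p": a}
         for e, a in zip(enr, adj)]
    ).to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    manifest["counts"][stage] = {"terms_tested": len(enr)}

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
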