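"""Call differential expression and test term enrichment.

NB Wald test per transcript between EF and NF buds at each stage,
Benjamini-Hochberg adjustment, and the printed thresholds adjusted
P < 0.01 with two-sided fold change >= 1.2; enriched terms are scored
with the exact hypergeometric upper tail.
"""

from lncforge import GeneratorConfig, simulate_study
from lncforge.expression import call_degs, de_test, enrich

study = simulate_study(GeneratorConfig(seed=42))
truth_de = set(study.truth.de_genes)

all_de = set()
for stage in ("Vb", "Tb", "Rb"):
    called = call_degs(de_test(study.counts, (f"EF-{stage}", f"NF-{stage}")))
    de = {r.transcript_id for r in called if r.is_de}
    all_de |= de
    hits = len(de & truth_de)
    print(f"NF-{stage} vs EF-{stage}: {len(de)} DE transcripts "
          f"({hits} of the {len(truth_de)} planted fold-change-2 genes)")

go = {}
for row in study.go_map.itertuples():
    go.setdefault(row.term_id, set()).add(row.gene_id)
population = {r.transcript_id for r in study.records}
results = sorted(enrich(all_de, population, go), key=lambda e: e.p)
print("\ntop enriched terms (hypergeometric P, smaller = more enriched):")
for e in results[:3]:
    mark = "  <- planted" if e.term_id in study.truth.enriched_terms else ""
    print(f"  {e.term_id}: m={e.input.m}/{e.input.n} sampled vs "
          f"M={e.input.M}/{e.input.N} population, P={e.p:.3g}{mark}")
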