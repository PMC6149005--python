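"""Classify lncRNA-mRNA positional relationships and find cis candidates.

Every overlapping pair falls into one of ten strand/containment
categories (e.g. an antisense lncRNA fully inside an mRNA intron); cis
candidates are mRNAs within 20 kb of a lncRNA.
"""

from collections import Counter

from lncforge import GeneratorConfig, simulate_study
from lncforge.geometry import classify_all, find_cis

study = simulate_study(GeneratorConfig(seed=42))
lncs = [r for r in study.records if r.biotype == "lncRNA"]
mrnas = [r for r in study.records if r.biotype == "mRNA"]

pairs = classify_all(lncs, mrnas)
print(f"{len(pairs)} overlapping lncRNA-mRNA pairs:")
for cat, n in sorted(Counter(p.category.value for p in pairs).items()):
    print(f"  {cat}: {n}")

n_cis = 0
for lnc in lncs:
    for c in find_cis(lnc, mrnas, window=20_000):
        n_cis += 1
        if c.distance != 0 and abs(c.distance) > 19_000:
            side = "upstream" if c.distance < 0 else "downstream"
            print(f"  near-boundary cis: {c.lnc_id} is {abs(c.distance)} nt "
                  f"{side} of {c.mrna_id}")
print(f"{n_cis} cis candidates within +/-20 kb (overlap counts as distance 0)")
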