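"""Driven extraction: find morphosyntactic variants of seed terms.

Scans a tiny hand-written corpus for windows containing all content
lemmas of each seed, classifying every hit as EXACT / INFLECTION /
INSERTION / PERMUTATION / EXPANSION.
"""

import bioterm as bt
from bioterm.variants import SeedTerm, find_variants, index_phrases

corpus_texts = [
    "the laboratory confirmation tests came back positive",
    "many diseases including infectious ones were monitored",
    "patients in the higher risk acute care area were isolated",
    "infectious diseases and infectious pulmonary diseases spread quickly",
]
index = index_phrases(bt.tag_corpus([(f"d{i}", t) for i, t in enumerate(corpus_texts)]))

for seed_text in ("laboratory tests", "infectious disease", "higher risk acute"):
    seed = SeedTerm.from_string(seed_text)
    print(f"seed: {seed_text!r}")
    for v in find_variants(seed, index):
        print(f"  {v.rule:<11} x{v.count}  {v.variant_surface!r}  (doc {v.doc_id})")
    print()

print(
    "INSERTION puts new words between the seed's words, PERMUTATION "
    "reorders them, EXPANSION extends the seed at an edge — recovering "
    "the full term 'higher risk acute care area' from its truncation."
)
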