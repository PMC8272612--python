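"""Combination strategies: representative, discriminant and new terms.

Intra-corpus: compare the two measures' top-K lists on one corpus — the
intersection C holds the most representative terms, the differences A/B
are discriminant per measure.  Inter-corpus: compare one measure across
the three segments — the three-way intersection D holds corpus-wide
common terms.  Both views are audited against a toy reference lexicon
(IN / VARIANT / NOT_IN).
"""

import bioterm as bt
from bioterm.lexicon import ReferenceLexicon, categorize_list
from bioterm.measures import C_VALUE, F_TFIDF_C_M
from bioterm.synthetic import example_spec, generate_corpus, generate_lexicon

spec = example_spec(seed=1)
docs, truth = generate_corpus(spec)
lexicon = ReferenceLexicon.from_terms(generate_lexicon(spec))
ranked = bt.free_extraction(docs, top_k=None)

K = 20
intra = bt.intra_corpus_combination(
    ranked["content"][C_VALUE], ranked["content"][F_TFIDF_C_M], lexicon=lexicon, k=K
)
print(f"intra-corpus (content, top-{K}):")
print(f"  C-Value only (A):      {len(intra.only_c_value)} terms")
print(f"  F-TFIDF-C only (B):    {len(intra.only_f_tfidf)} terms")
print(f"  both = representative: {sorted(intra.common)}")

inter = bt.inter_corpus_combination({s: ranked[s][C_VALUE] for s in ranked}, k=K)
pct = bt.overlap_percentages(inter)
print(f"\ninter-corpus (C-Value, top-{K}):")
print(f"  title terms also in abstract: {pct['title_in_abstract']}%")
print(f"  title terms also in content:  {pct['title_in_content']}%")
print(f"  common to all three (D):      {sorted(inter.common)}")

report = categorize_list(ranked["content"][C_VALUE].terms(K), lexicon)
print(f"\nlexicon trichotomy of the content top-{K} (C-Value):")
for label in ("IN", "VARIANT", "NOT_IN"):
    print(f"  {label:<8} {report.counts[label]:3d}  ({report.percentages[label]:.0f}%)")

print(
    "\nD-set terms recur in every segment, so they summarize the corpus; "
    "NOT_IN terms are candidates for new domain terminology."
)
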