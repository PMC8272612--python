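"""Scalable ranking: partition a corpus and compose average ranks.

Large corpora are chunked into fixed-size sub-corpora, each ranked
independently, and the per-chunk lists recombined by averaging each
term's 1-based rank over the chunks containing it (best = lowest mean).
"""

import bioterm as bt
from bioterm.measures import C_VALUE
from bioterm.synthetic import example_spec, generate_corpus

docs, truth = generate_corpus(example_spec(seed=1))
corpus = bt.segment_corpus(docs, "abstract")

part = bt.partition_corpus(corpus, chunk_size=6)
print(f"{len(corpus)} abstracts partitioned into chunks of {part.sizes()} documents")
print("(an undersized final remainder is merged into the preceding chunk)\n")

composed = bt.rank_corpus_partitioned(corpus, chunk_size=6, measures=(C_VALUE,), top_k=5)
print("top 5 by composed mean rank (score column = mean rank, lower is better):")
for term, mean_rank, position in composed[C_VALUE].entries:
    print(f"  {position:2d}  mean_rank={mean_rank:6.2f}  {term}")

whole = bt.rank_corpus(corpus, measures=(C_VALUE,), top_k=5)
print("\ntop 5 ranking the whole corpus at once, for comparison:")
for term, score, rank in whole[C_VALUE].entries:
    print(f"  {rank:2d}  score={score:9.2f}  {term}")
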