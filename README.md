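# bioterm

Terminology extraction and analysis for biomedical corpora.

Given a corpus of paper-like documents (title / abstract / content),
`bioterm` answers three questions a domain analyst — for instance someone
curating surveillance keywords for epidemic intelligence — keeps asking:

1. **Which terms represent this corpus?** *Free extraction*: every token
   window of 1–4 words matching a part-of-speech pattern (e.g. `NN NN`,
   `JJ NN NN`) becomes a candidate term, ranked by statistical termhood
   measures.
2. **Which terms are specific to one view of the corpus, and which are
   shared?** *Combination strategies*: top-K lists are compared across
   measures (intra-corpus) and across the title/abstract/content segments
   (inter-corpus), yielding discriminant sets, pairwise intersections and
   a corpus-wide common set.
3. **What variants of a known term hide in the text?** *Driven
   extraction*: windows containing all content lemmas of a seed term are
   classified as EXACT / INFLECTION / INSERTION / PERMUTATION /
   EXPANSION — recovering, say, `laboratory confirmation tests` from the
   seed `laboratory tests`, or the full `higher risk acute care area`
   from a truncated extraction.

Extracted terms are audited against any flat reference lexicon (stand-in
for a terminology resource such as the UMLS Metathesaurus) with a
three-way verdict: `IN` (exact normalized match), `VARIANT`
(order-insensitive content-word containment either way), `NOT_IN`
(candidate new terminology).

## The measures

For a candidate term *a* of length |*a*| words with corpus frequency
*f(a)*, and *T_a* the set of longer candidates containing *a*:

```
C-Value(a) = log2(|a|+1) · f(a)                              if T_a = ∅
C-Value(a) = log2(|a|+1) · ( f(a) − (1/|T_a|) Σ_{b∈T_a} f(b) )  otherwise
TF-IDF(a)  = mean over documents d containing a of  tf_d(a) · log2(N/df(a))
F-TFIDF-C(a) = harmonic mean of C-Value(a) and TF-IDF(a)
```

C-Value favors cohesive multi-word terms (nested candidates like `virus`
inside `influenza virus` are penalized by their containers); TF-IDF
favors terms concentrated in few documents; the harmonic mean balances
the two. The `|a|+1` inside the log keeps single-word terms rankable.
Large corpora are partitioned into fixed-size sub-corpora, ranked per
chunk, and recombined by each term's average rank position.

## Worked example

```bash
python examples/01_free_extraction.py
```

builds a 16-document synthetic corpus with a dominant planted term and
prints, per segment, the C-Value top of the list:

```
--- title: top 5 by C-Value ---
   1     124.69  influenza virus
   2      78.51  virus
   3      78.50  influenza
   4      45.47  health emergency
   5      35.92  close contact
```

`influenza virus` (planted 80×) ranks first: its score is
log2(3)·(80 − mean container frequency), ahead of its own nested
unigrams whose C-Value is log2(2)·f minus the container correction.
`examples/03_combination_strategies.py` continues the analysis:

```
inter-corpus (C-Value, top-20):
  title terms also in abstract: 45%
  title terms also in content:  20%
  common to all three (D):      ['health emergency', 'influenza', 'influenza virus', 'virus']

lexicon trichotomy of the content top-20 (C-Value):
  IN         1  (5%)
  VARIANT    3  (15%)
  NOT_IN    16  (80%)
```

The D set holds terms recurring in every segment — the corpus's common
vocabulary; `NOT_IN` terms are candidates for new terminology. The other
examples demonstrate driven variant extraction (`02`) and partitioned
ranking with average-rank composition (`04`).

A thin CLI wraps the same pipeline for shell use:

```bash
bioterm simulate --seed 3 --out-dir fixture
bioterm extract-free fixture/corpus.jsonl --lexicon fixture/lexicon.txt --out-dir ranked
bioterm extract-driven fixture/corpus.jsonl --seeds seeds.txt --lexicon fixture/lexicon.txt
bioterm combine --mode inter --ranked ranked/title_c_value.tsv \
    --ranked ranked/abstract_c_value.tsv --ranked ranked/content_c_value.tsv
```

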