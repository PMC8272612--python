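# Methods

## Pipeline overview

A corpus is a list of documents with up to three text fields: title,
abstract, content. Each stage is a pure function of its inputs, so every
run is reproducible:

1. **Segmentation** projects the corpus onto one field; documents with an
   empty field are dropped from that segment (scientific corpora
   routinely lack abstracts), not rejected.
2. **Tagging** maps text to (surface, lemma, Penn tag) tokens. The
   contract is pluggable; the built-in `RuleTagger` is a deterministic
   closed-class-lexicon + suffix tagger with rule-based plural
   lemmatization and a small irregular table. Hyphenated compounds are
   split; sentence boundaries (`. ! ? ;`, blank lines) are recorded and
   never crossed by any window.
3. **Candidate extraction** emits every token window of `ngram_min..4`
   words whose tag sequence matches a configured pattern — including
   nested windows, which the C-Value correction requires. Occurrences
   group case-insensitively by lemma sequence; the displayed surface is
   the modal realization.
4. **Scoring and ranking** computes C-Value, TF-IDF and their harmonic
   mean per candidate and sorts descending with deterministic
   tie-breaking (score, then frequency, then lemma key).
5. **Combination** intersects top-K lists across measures and segments;
   **lexicon categorization** audits any term list; **driven extraction**
   finds seed-term variants.

## C-Value

With `T_a` the set of longer candidates containing `a` as a contiguous
lemma subsequence:

    C-Value(a) = log2(|a|+1) * f(a)                                 if T_a empty
    C-Value(a) = log2(|a|+1) * ( f(a) - (1/|T_a|) * sum_b f(b) )    otherwise

Two deliberate choices:

* **Length weight `log2(|a|+1)`** rather than the classical
  `log2(|a|)`. The classical weight zeroes every single-word term, but
  this toolkit ranks SWT lists with C-Value too; `+1` is the minimal
  modification that keeps unigrams scoreable while preserving the
  preference for longer terms.
* **Clamping at 0.** When a term's containers jointly outnumber its own
  occurrences the corrected score would go negative; it is clamped so the
  harmonic mean stays defined. `clamp=False` exposes the raw value.

## TF-IDF and the harmonic mean

Per containing document, `tf_d(a) * log2(N / df(a))` with N the segment's
document count. The term-level score aggregates by arithmetic mean over
containing documents (`agg="max"` is available; the mean is the default
because a single outlier document should not dominate a corpus-level
score). Logarithms are base 2 throughout for internal consistency.
`F-TFIDF-C(c, t) = 2ct/(c+t)`, defined as 0 when both inputs are 0; it is
symmetric and bounded by min and max of its arguments.

## Partitioned ranking

Corpora too large to score in one pass are chunked sequentially at
`chunk_size` documents. An undersized final remainder is merged into the
preceding chunk by default (`merge_last`), so 9315 documents at 1000 per
chunk yield 8×1000 + 1×1315 rather than a 315-document tail. Per-chunk
ranked lists are recombined by each term's mean 1-based rank over the
chunks containing it, sorted ascending; a term absent from a chunk simply
contributes nothing there (no absence penalty), and the per-term support
count is reported so callers can filter low-support terms. Averaging
rank positions rather than raw scores makes chunks of different sizes
commensurable; `on="score"` exposes the alternative.

## POS patterns

Pattern files hold one space-separated pattern per line, 1–4 symbols,
`#` comments, priority = file order. The symbol alphabet is compressed:
`NN` matches {NN, NNS}, `NP` {NNP, NNPS}, `JJ` {JJ, JJR, JJS}, `RB`
{RB, RBR, RBS}; any other symbol matches its exact Penn tag. The shipped
default file holds 50 patterns (4 unigram, 12 bigram, 17 trigram, 17
four-gram; noun phrases, adjective-noun compounds, prepositional
compounds like `NN IN NN`, and verb-bridged patterns like `NN VBD NN
NN`) and is fully user-replaceable. Pattern priority is recorded on each
candidate but does not enter scoring.

## Variant taxonomy

A window qualifies for a seed when it contains all the seed's content
lemmas, starts and ends on content tokens, stays within one sentence,
and is at most `len(seed) + max_insertions + max_expansion` tokens
(defaults 2 + 2 — a total extra-token budget, sized to recover the
longest documented expansion cases without unbounded windows).
Classification compares the window's content-lemma sequence to the
seed's:

| condition | label |
|---|---|
| same lemmas in order, same surfaces | EXACT |
| same lemmas in order, surfaces differ | INFLECTION |
| seed order preserved, extra content between seed lemmas | INSERTION |
| seed order preserved, extras only at the edges | EXPANSION |
| seed order not preserved | PERMUTATION |

The in-order check is a greedy left-to-right subsequence match, so with
repeated lemmas the leftmost binding decides the label. Function words
(including connectives such as "including") never count as seed lemmas
but may appear freely as inserted material; matching is lemma-level and
case-insensitive. Variants deduplicate by (lemma sequence, rule) with
occurrence counts and are ordered count-descending then shorter-first —
a simple relevance index, since a single seed can yield hundreds of raw
windows. Only inflectional morphology is matched; derivational variants
(noun↔adjective) are out of scope.

## Lexicon trichotomy

Lexicon entries and query terms share one normalization: lowercase,
hyphen split, punctuation strip, rule-based singularization, stop-word
removal. `IN` = exact normalized match. `VARIANT` = the term's
content-lemma bag is a strict subset of some entry's bag or vice versa;
bag (order-insensitive) containment is used because reordered sub-terms
("health emergency" inside "Emergency Health Services") must match. A
single-word term can be VARIANT only through containment in a multi-word
entry; letting unigrams match by *containing* an entry would inflate the
VARIANT class with every word of every entry. Precedence IN > VARIANT >
NOT_IN is enforced.

## Synthetic fixtures

The generator emulates the statistical structure the pipeline is
sensitive to, not English: a closed filler vocabulary of nouns (fixed
tags under the rule tagger), per-segment document lengths in realistic
ratio (defaults 15 / 180 / 460 words, roughly a tenth of typical
scientific-paper scale), and planted terms at exact corpus frequencies,
inserted as atomic units so later insertions cannot split earlier ones
and ground truth recounts exactly. Each planted term carries a lexicon
plan (IN / VARIANT / NOT_IN) that the toy-lexicon generator realizes and
validates; an unrealizable plan (e.g. NOT_IN for a term nested inside an
IN term's bag) raises with the term named. The default study conditions
(`example_spec`): 16 documents, 200 filler lemmas, a dominant in-lexicon
bigram planted 80× per segment, a lexicon-variant bigram 30×, a novel
bigram 24×, and a 6× content-only insertion variant of the dominant term
for driven extraction to recover. Sizes are chosen so the dominant
term's C-Value clearly exceeds the most frequent filler unigram in every
segment while the whole pipeline runs in seconds.

Passing tests on these fixtures demonstrate the algebra and the
end-to-end wiring — planted-term recovery, exact frequency accounting,
label plans — not performance on real prose: real corpora bring tagger
error, morphology the rule lemmatizer misses, and skewed document
lengths that the generator does not emulate.

## Numerical and degenerate-input choices

* Log base 2 everywhere (a module constant).
* Ranked-list ties break score desc → frequency desc → lemma key asc;
  composed-ranking ties break mean rank asc → support desc → lemma key.
* Harmonic mean of (0, 0) is 0; negative inputs are errors.
* `tf_idf` requires `doc_freq ≥ 1` and `n_docs ≥ doc_freq`.
* Empty text tags to an empty token list; an empty corpus extracts no
  candidates; overlap percentages on an empty title set are reported as
  undefined (None), not an error.
* Percentages in combination reports round half-up to integers; the
  trichotomy report keeps float percentages.
* Non-Penn tags from injected taggers map to a catch-all tag with a
  logged warning rather than failing the document.

## Known limitations

* The rule tagger trades accuracy for determinism; suffix heuristics
  mistag some nouns as adjectives and vice versa. For production use,
  inject a statistical Penn tagger.
* Rule-based singularization handles regular plurals and a fixed
  irregular table only.
* Variant search is exhaustive within its window budget; extremely long
  seeds with common words can still generate many windows (the count/
  length ordering mitigates, not eliminates, this).
* Lexicon VARIANT matching is bag containment, not semantic mapping; it
  neither uses nor approximates concept identifiers.
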