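"""High-level free-extraction pipeline used by the CLI, examples and tests.

Wires segment -> (optional partition) -> tag -> extract -> score -> rank,
returning one ranked list per requested measure.  When a chunk size is
given the corpus is partitioned, each chunk ranked independently and the
chunk lists recombined by average rank; the composed list is re-labelled
with 1-based positions so downstream set operations treat both paths
uniformly.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Sequence

from .corpus import Document, Segment, SegmentedCorpus, partition_corpus, segment_corpus
from .extraction import CandidateTerm, PosPattern, default_patterns, extract_candidates
from .measures import (
    MEASURES,
    RankedTermList,
    compose_partition_ranks,
    rank_terms,
    score_candidates,
)
from .tagging import Tagger, tag_corpus

logger = logging.getLogger(__name__)


def candidates_for_corpus(
    corpus: SegmentedCorpus,
    patterns: Sequence[PosPattern] | None = None,
    tagger: Tagger | None = None,
    ngram_min: int = 1,
    ngram_max: int = 4,
) -> List[CandidateTerm]:
    tagged = tag_corpus(corpus.documents, tagger)
    return extract_candidates(tagged, patterns or default_patterns(), ngram_min, ngram_max)


def rank_corpus(
    corpus: SegmentedCorpus,
    measures: Sequence[str] = MEASURES,
    patterns: Sequence[PosPattern] | None = None,
    tagger: Tagger | None = None,
    top_k: int | None = None,
    ngram_min: int = 1,
    ngram_max: int = 4,
    tfidf_agg: str = "mean",
) -> Dict[str, RankedTermList]:
    """Rank one segmented corpus under each requested measure."""
    candidates = candidates_for_corpus(corpus, patterns, tagger, ngram_min, ngram_max)
    stats = score_candidates(candidates, n_docs=len(corpus), tfidf_agg=tfidf_agg)
    return {
        m: rank_terms(stats, m, top_k=top_k, source=corpus.label) for m in measures
    }


def rank_corpus_partitioned(
    corpus: SegmentedCorpus,
    chunk_size: int,
    measures: Sequence[str] = MEASURES,
    patterns: Sequence[PosPattern] | None = None,
    tagger: Tagger | None = None,
    top_k: int | None = None,
    merge_last: bool = True,
    **kwargs,
) -> Dict[str, RankedTermList]:
    """Partitioned scoring with average-rank composition per measure."""
    partition = partition_corpus(corpus, chunk_size, merge_last=merge_last)
    logger.info("partitioned %s into %d chunk(s): %s", corpus.label, len(partition), partition.sizes())
    per_measure: Dict[str, List[RankedTermList]] = {m: [] for m in measures}
    for chunk in partition.chunks:
        ranked = rank_corpus(chunk, measures, patterns, tagger, top_k=None, **kwargs)
        for m in measures:
            per_measure[m].append(ranked[m])
    out: Dict[str, RankedTermList] = {}
    for m in measures:
        composed = compose_partition_ranks(per_measure[m])
        entries = composed.entries if top_k is None else composed.entries[:top_k]
        # re-label with 1-based positions; score column carries the mean rank
        out[m] = RankedTermList(
            measure=m,
            entries=tuple(
                (term, mean_rank, pos)
                for pos, (term, mean_rank, _) in enumerate(entries, start=1)
            ),
            source=corpus.label,
        )
    return out


def free_extraction(
    docs: Sequence[Document],
    segments: Sequence[str | Segment] = tuple(Segment),
    measures: Sequence[str] = MEASURES,
    chunk_size: int | None = None,
    **kwargs,
) -> Dict[str, Dict[str, RankedTermList]]:
    """Segment the corpus and rank every (segment, measure) pair."""
    out: Dict[str, Dict[str, RankedTermList]] = {}
    for segment in segments:
        corpus = segment_corpus(docs, segment)
        if chunk_size:
            out[corpus.label] = rank_corpus_partitioned(corpus, chunk_size, measures, **kwargs)
        else:
            out[corpus.label] = rank_corpus(corpus, measures, **kwargs)
    return out
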