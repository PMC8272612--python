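"""Termhood measures and ranked-list construction.

Three scores are computed per candidate term *a* with corpus frequency
f(a) over a segmented corpus of N documents:

* **C-Value** — frequency weighted by term length, corrected for nesting.
  With T_a the set of longer candidate terms containing *a* as a
  contiguous lemma subsequence::

      C-Value(a) = log2(|a| + 1) * f(a)                              if T_a = {}
      C-Value(a) = log2(|a| + 1) * ( f(a) - (1/|T_a|) * sum_b f(b) ) otherwise

  The ``|a| + 1`` inside the log keeps single-word terms scoreable
  (the classical log2(|a|) weight zeroes them out), which is required for
  ranking SWT lists.  A nested correction larger than f(a) would drive
  the score negative; it is clamped at 0 so the harmonic mean below stays
  defined.

* **TF-IDF** — per containing document d, tf_d(a) * log2(N / df(a)); the
  term-level score aggregates over containing documents (arithmetic mean
  by default, max available).

* **F-TFIDF-C** — the harmonic mean of the two, balancing unithood
  (C-Value) against discriminativity (TF-IDF); 0 whenever either input
  is 0.

Large corpora are scored per sub-corpus chunk and the per-chunk ranked
lists recombined by average rank position (``compose_partition_ranks``).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

from .extraction import CandidateTerm

C_VALUE = "C_VALUE"
TFIDF = "TFIDF"
F_TFIDF_C_M = "F_TFIDF_C_M"
MEASURES = (C_VALUE, TFIDF, F_TFIDF_C_M)

LOG_BASE = 2.0


def _log(x: float) -> float:
    return math.log(x, LOG_BASE)


@dataclass
class TermStatistics:
    """One candidate with its container set T_a and the three scores."""

    candidate: CandidateTerm
    nested_in: Set[str] = field(default_factory=set)
    c_value: float = 0.0
    tfidf: float = 0.0
    f_tfidf_c_m: float = 0.0

    def score(self, measure: str) -> float:
        if measure == C_VALUE:
            return self.c_value
        if measure == TFIDF:
            return self.tfidf
        if measure == F_TFIDF_C_M:
            return self.f_tfidf_c_m
        raise ValueError(f"unknown measure {measure!r}")


@dataclass(frozen=True)
class RankedTermList:
    """Measure-labelled (term, score, 1-based rank) list for one corpus."""

    measure: str
    entries: Tuple[Tuple[str, float, int], ...]
    source: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def terms(self, k: int | None = None) -> List[str]:
        sliced = self.entries if k is None else self.entries[:k]
        return [term for term, _, _ in sliced]


@dataclass(frozen=True)
class ComposedRanking:
    """Average-rank recombination of per-chunk lists.

    ``support`` counts the sub-corpora a term appeared in; absent chunks
    contribute nothing to the mean.
    """

    measure: str
    entries: Tuple[Tuple[str, float, int], ...]  # (lemma_key, mean_rank, support)

    def __len__(self) -> int:
        return len(self.entries)

    def terms(self, k: int | None = None) -> List[str]:
        sliced = self.entries if k is None else self.entries[:k]
        return [term for term, _, _ in sliced]


# --- nesting ----------------------------------------------------------------


def compute_nesting(candidates: Sequence[CandidateTerm]) -> Dict[str, Set[str]]:
    """Map each lemma_key to the set T_a of longer candidates containing it.

    Containment is contiguous-subsequence on the lemma tuples; built by
    enumerating each candidate's sub-windows against the candidate set,
    O(n * L^2) for max length L.
    """
    keys = {c.lemmas: c.lemma_key for c in candidates}
    nested_in: Dict[str, Set[str]] = {c.lemma_key: set() for c in candidates}
    for container in candidates:
        lemmas = container.lemmas
        length = len(lemmas)
        for sub_len in range(1, length):
            for start in range(length - sub_len + 1):
                sub = lemmas[start : start + sub_len]
                key = keys.get(sub)
                if key is not None:
                    nested_in[key].add(container.lemma_key)
    return nested_in


# --- the three measures -----------------------------------------------------


def c_value(
    candidate: CandidateTerm,
    nesting: Mapping[str, Set[str]],
    freqs: Mapping[str, int],
    clamp: bool = True,
) -> float:
    """Length-weighted, nesting-corrected termhood score (see module docs)."""
    if candidate.lemma_key not in freqs:
        raise KeyError(f"candidate {candidate.lemma_key!r} missing from frequency map")
    weight = _log(candidate.length + 1)
    containers = nesting.get(candidate.lemma_key, set())
    if not containers:
        score = weight * candidate.freq
    else:
        correction = sum(freqs[b] for b in containers) / len(containers)
        score = weight * (candidate.freq - correction)
    if clamp and score < 0.0:
        score = 0.0
    return score


def tf_idf(candidate: CandidateTerm, n_docs: int, agg: str = "mean") -> float:
    """Aggregated tf*idf over the documents containing the candidate."""
    df = candidate.doc_freq
    if df < 1:
        raise ValueError(f"candidate {candidate.lemma_key!r} has doc_freq < 1")
    if n_docs < df:
        raise ValueError(f"n_docs={n_docs} < doc_freq={df} for {candidate.lemma_key!r}")
    idf = _log(n_docs / df)
    per_doc = [tf * idf for tf in candidate.per_doc_tf.values()]
    if agg == "mean":
        return sum(per_doc) / len(per_doc)
    if agg == "max":
        return max(per_doc)
    raise ValueError(f"unknown tf-idf aggregation {agg!r}")


def f_tfidf_c_m(c_val: float, tfidf_val: float) -> float:
    """Harmonic mean of a C-Value and a TF-IDF score; 0 if both are 0."""
    if c_val < 0 or tfidf_val < 0:
        raise ValueError("harmonic mean inputs must be >= 0")
    if c_val == 0.0 and tfidf_val == 0.0:
        return 0.0
    return 2.0 * c_val * tfidf_val / (c_val + tfidf_val)


def score_candidates(
    candidates: Sequence[CandidateTerm], n_docs: int, tfidf_agg: str = "mean"
) -> List[TermStatistics]:
    """Compute nesting plus all three scores for every candidate."""
    nesting = compute_nesting(candidates)
    freqs = {c.lemma_key: c.freq for c in candidates}
    stats: List[TermStatistics] = []
    for cand in candidates:
        cv = c_value(cand, nesting, freqs)
        ti = tf_idf(cand, n_docs, agg=tfidf_agg)
        stats.append(
            TermStatistics(
                candidate=cand,
                nested_in=nesting[cand.lemma_key],
                c_value=cv,
                tfidf=ti,
                f_tfidf_c_m=f_tfidf_c_m(cv, ti),
            )
        )
    return stats


# --- ranking and composition ------------------------------------------------


def rank_terms(
    stats: Sequence[TermStatistics],
    measure: str,
    top_k: int | None = None,
    source: str = "",
) -> RankedTermList:
    """Sort by score descending into a 1-based ranked list.

    Ties break by frequency descending then lemma_key, so ranking is a
    pure function of the statistics.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    ordered = sorted(
        stats, key=lambda s: (-s.score(measure), -s.candidate.freq, s.candidate.lemma_key)
    )
    if top_k is not None:
        ordered = ordered[:top_k]
    entries = tuple(
        (s.candidate.lemma_key, s.score(measure), rank)
        for rank, s in enumerate(ordered, start=1)
    )
    return RankedTermList(measure=measure, entries=entries, source=source)


def compose_partition_ranks(
    per_chunk: Sequence[RankedTermList], on: str = "rank"
) -> ComposedRanking:
    """Combine per-chunk ranked lists by each term's average rank position.

    A term's composed value is the mean of its 1-based ranks over the
    chunks where it appears; the result is sorted ascending (best first).
    ``on="score"`` averages raw scores instead (then sorted descending).
    """
    if not per_chunk:
        raise ValueError("at least one ranked list is required")
    measures = {lst.measure for lst in per_chunk}
    if len(measures) > 1:
        raise ValueError(f"mixed measures in composition: {sorted(measures)}")
    if on not in ("rank", "score"):
        raise ValueError(f"unknown composition basis {on!r}")
    values: Dict[str, List[float]] = defaultdict(list)
    for lst in per_chunk:
        for term, score, rank in lst.entries:
            values[term].append(float(rank) if on == "rank" else score)
    composed = [
        (term, sum(vals) / len(vals), len(vals)) for term, vals in values.items()
    ]
    if on == "rank":
        composed.sort(key=lambda e: (e[1], -e[2], e[0]))
    else:
        composed.sort(key=lambda e: (-e[1], -e[2], e[0]))
    return ComposedRanking(measure=per_chunk[0].measure, entries=tuple(composed))


def write_ranked_tsv(
    ranked: RankedTermList,
    path: str | Path,
    in_lexicon: Mapping[str, bool] | None = None,
) -> None:
    """TSV writer with columns term, in_lexicon (0/1), rank, score."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("term\tin_lexicon\trank\tscore\n")
        for term, score, rank in ranked.entries:
            flag = "" if in_lexicon is None else str(int(in_lexicon.get(term, False)))
            handle.write(f"{term}\t{flag}\t{rank}\t{score:.4f}\n")
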