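"""Driven extraction: morphosyntactic variants of seed terms.

Given a seed term (e.g. "laboratory tests"), the corpus is scanned for
token windows that contain every content lemma of the seed, within a
length budget.  Each qualifying window is classified by how it deviates
from the seed:

* ``EXACT`` — same content lemmas in order, same surfaces;
* ``INFLECTION`` — same content lemmas in order, surfaces differ
  ("infectious diseases" for "infectious disease");
* ``INSERTION`` — seed lemma order preserved with extra content words
  between seed lemmas ("laboratory confirmation tests");
* ``PERMUTATION`` — seed lemma order changed ("diseases including
  infectious": the connective is a function word, the content order is
  reversed);
* ``EXPANSION`` — order preserved, no internal insertions, extra content
  attached at an edge ("higher risk acute" -> "higher risk acute care
  area"), recovering full terms from truncated ones.

Function words never count as seed lemmas but may appear freely as
inserted material.  Windows are trimmed to start and end on content
tokens (otherwise each match would spawn a halo of stop-word-padded
duplicates), never cross sentence boundaries, and are capped at
``len(seed) + max_insertions + max_expansion`` tokens.  Variants are
deduplicated by (lemma sequence, rule) with occurrence counts, then
ordered count-descending / shorter-first as a simple relevance index —
a single seed can otherwise yield hundreds of raw windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

from ._stopwords import STOP_WORDS
from .lexicon import ReferenceLexicon, normalize_term
from .tagging import TaggedToken

logger = logging.getLogger(__name__)

EXACT = "EXACT"
INFLECTION = "INFLECTION"
INSERTION = "INSERTION"
PERMUTATION = "PERMUTATION"
EXPANSION = "EXPANSION"
RULES = (EXACT, INFLECTION, INSERTION, PERMUTATION, EXPANSION)

DEFAULT_MAX_INSERTIONS = 2
DEFAULT_MAX_EXPANSION = 2


@dataclass(frozen=True)
class SeedTerm:
    """A driving term reduced to its content lemmas."""

    lemma_seq: Tuple[str, ...]
    surface: str

    def __post_init__(self) -> None:
        if not self.lemma_seq:
            raise ValueError(f"seed {self.surface!r} has no content lemma")

    def __len__(self) -> int:
        return len(self.lemma_seq)

    @classmethod
    def from_string(cls, text: str) -> "SeedTerm":
        return cls(lemma_seq=normalize_term(text), surface=text.strip())


@dataclass
class TermVariant:
    """One deduplicated variant occurrence set for a seed."""

    seed: SeedTerm
    variant_surface: str
    rule: str
    doc_id: str
    span: Tuple[int, int]  # half-open token interval in doc
    count: int = 1
    in_lexicon: bool | None = None


@dataclass
class PhraseIndex:
    """Content-lemma -> (doc index, token position) postings over a corpus."""

    docs: List[Tuple[str, Sequence[TaggedToken]]]
    postings: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)

    def lookup(self, lemma: str) -> List[Tuple[int, int]]:
        return self.postings.get(lemma, [])


def index_phrases(tagged_docs: Sequence[Tuple[str, Sequence[TaggedToken]]]) -> PhraseIndex:
    index = PhraseIndex(docs=list(tagged_docs))
    for doc_idx, (_, tokens) in enumerate(index.docs):
        for tok in tokens:
            if not tok.is_stop:
                index.postings.setdefault(tok.lemma, []).append((doc_idx, tok.position))
    return index


def _content(window: Sequence[TaggedToken]) -> List[TaggedToken]:
    return [t for t in window if not t.is_stop]


def classify_variant(seed: SeedTerm, window: Sequence[TaggedToken]) -> str:
    """Assign the variant rule for a window containing all seed lemmas."""
    content = _content(window)
    lemmas = [t.lemma for t in content]
    missing = [s for s in seed.lemma_seq if s not in lemmas]
    if missing:
        raise ValueError(f"window lacks seed lemma(s) {missing} for seed {seed.surface!r}")
    if tuple(lemmas) == seed.lemma_seq:
        seed_surfaces = [w.lower() for w in seed.surface.replace("-", " ").split() if w.lower() not in STOP_WORDS]
        surfaces = [t.surface.lower() for t in content]
        return EXACT if surfaces == seed_surfaces else INFLECTION
    order = _seed_order(seed.lemma_seq, lemmas)
    if order is None:
        return PERMUTATION
    first, last = order[0], order[-1]
    internal_extra = (last - first + 1) > len(seed.lemma_seq)
    if internal_extra:
        return INSERTION
    return EXPANSION


def _seed_order(seed: Tuple[str, ...], lemmas: List[str]) -> List[int] | None:
    """Positions of the seed lemmas appearing in order, or None if reordered.

    Greedy left-to-right match of the seed sequence against the window's
    content lemmas (a subsequence check).
    """
    positions: List[int] = []
    start = 0
    for s in seed:
        try:
            idx = lemmas.index(s, start)
        except ValueError:
            return None
        positions.append(idx)
        start = idx + 1
    return positions


def find_variants(
    seed: SeedTerm,
    index: PhraseIndex,
    max_insertions: int = DEFAULT_MAX_INSERTIONS,
    max_expansion: int = DEFAULT_MAX_EXPANSION,
) -> List[TermVariant]:
    """All deduplicated variants of one seed in the indexed corpus."""
    max_len = len(seed) + max_insertions + max_expansion
    # restrict to documents containing every seed lemma
    doc_sets = []
    for lemma in set(seed.lemma_seq):
        doc_sets.append({doc for doc, _ in index.lookup(lemma)})
    candidate_docs = set.intersection(*doc_sets) if doc_sets else set()

    grouped: Dict[Tuple[Tuple[str, ...], str], TermVariant] = {}
    for doc_idx in sorted(candidate_docs):
        doc_id, tokens = index.docs[doc_idx]
        for window in _qualifying_windows(seed, tokens, max_len):
            rule = classify_variant(seed, window)
            key = (tuple(t.lemma for t in window), rule)
            surface = " ".join(t.surface for t in window)
            existing = grouped.get(key)
            if existing is None:
                grouped[key] = TermVariant(
                    seed=seed,
                    variant_surface=surface,
                    rule=rule,
                    doc_id=doc_id,
                    span=(window[0].position, window[-1].position + 1),
                    count=1,
                )
            else:
                existing.count += 1
    variants = list(grouped.values())
    # relevance ordering: frequent first, then shorter, then surface
    variants.sort(key=lambda v: (-v.count, v.span[1] - v.span[0], v.variant_surface.lower()))
    return variants


def _qualifying_windows(
    seed: SeedTerm, tokens: Sequence[TaggedToken], max_len: int
) -> Iterable[Sequence[TaggedToken]]:
    """Windows of length |seed|..max_len containing all seed content lemmas.

    Windows start and end on content tokens and stay within one sentence.
    """
    needed = set(seed.lemma_seq)
    n = len(tokens)
    for start in range(n):
        if tokens[start].is_stop:
            continue
        for end in range(start + len(seed), min(start + max_len, n) + 1):
            window = tokens[start:end]
            if window[-1].is_stop:
                continue
            if window[-1].sentence != window[0].sentence:
                break
            lemmas = {t.lemma for t in window if not t.is_stop}
            if needed <= lemmas:
                yield window


def filter_new_variants(
    variants: List[TermVariant], lexicon: ReferenceLexicon
) -> List[TermVariant]:
    """Annotate each variant's lexicon membership; return the new (absent) ones.

    The full input list keeps its ``in_lexicon`` flags for reporting, so
    in-lexicon variants can still be displayed (highlighted) alongside.
    """
    new: List[TermVariant] = []
    for variant in variants:
        variant.in_lexicon = variant.variant_surface in lexicon
        if not variant.in_lexicon:
            new.append(variant)
    return new


def load_seeds(path: str | Path) -> List[SeedTerm]:
    """One seed term per line, UTF-8; blank lines and ``#`` comments skipped."""
    seeds = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            body = line.split("#", 1)[0].strip()
            if body:
                seeds.append(SeedTerm.from_string(body))
    return seeds


def write_variants_tsv(variants: Iterable[TermVariant], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("seed\tvariant\trule\tcount\tin_lexicon\tdoc_id\n")
        for v in variants:
            flag = "" if v.in_lexicon is None else str(int(v.in_lexicon))
            handle.write(f"{v.seed.surface}\t{v.variant_surface}\t{v.rule}\t{v.count}\t{flag}\t{v.doc_id}\n")
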