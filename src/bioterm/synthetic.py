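"""Deterministic synthetic corpora with planted terms and a toy lexicon.

The generator emulates the statistical structure the pipeline cares
about — per-segment document-length ratios (short titles, medium
abstracts, long contents), a closed filler vocabulary of noun tokens, and
planted multi-word terms at controlled corpus frequencies — not
linguistically realistic English.  Every filler lemma carries a fixed
noun tag under the built-in rule tagger, so extraction behavior does not
depend on any statistical model.

Each planted term carries a lexicon *plan* (IN / VARIANT / NOT_IN) that
``generate_lexicon`` realizes: IN terms appear verbatim in the toy
lexicon, VARIANT terms appear only inside a longer reordered entry
(emulating "health emergency" being part of "Emergency Health Services"),
NOT_IN terms are absent.  The returned :class:`FixtureTruth` records the
realized frequencies and expected labels so end-to-end tests can assert
against ground truth.

All generation is a pure function of the spec (including its seed): the
same spec yields byte-identical corpora.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

from .corpus import Document, Segment
from .lexicon import IN, NOT_IN, VARIANT, ReferenceLexicon, categorize_term

ALL_SEGMENTS = (Segment.TITLE.value, Segment.ABSTRACT.value, Segment.CONTENT.value)

# filler nouns chosen so the rule tagger assigns NN and lemma == word
_BASE_NOUNS = """
gene cell protein genome sample cohort assay buffer enzyme tissue serum
plasma antibody antigen vaccine outbreak pathogen host vector strain
mutation receptor membrane nucleus kinase ligand molecule pathway sequence
marker probe primer culture medium dose titer spike capsid helix codon
exon intron ribosome peptide lipid glucose neuron synapse cortex lesion
tumor biopsy plasmid clone colony substrate isolate lysate extract pellet
aliquot flask slide
""".split()


@dataclass(frozen=True)
class PlantedTerm:
    """A term planted at a fixed per-segment corpus frequency."""

    lemmas: Tuple[str, ...]
    freq: int
    segments: Tuple[str, ...] = ALL_SEGMENTS
    lexicon_plan: str = IN

    @property
    def lemma_key(self) -> str:
        return " ".join(self.lemmas)


@dataclass(frozen=True)
class FixtureSpec:
    """Full recipe for one synthetic corpus + lexicon pair."""

    n_docs: int = 16
    planted_terms: Tuple[PlantedTerm, ...] = ()
    vocab_size: int = 200
    seed: int = 0
    title_len: int = 15
    abstract_len: int = 180
    content_len: int = 460

    def segment_length(self, segment: str) -> int:
        return {"title": self.title_len, "abstract": self.abstract_len, "content": self.content_len}[segment]


@dataclass
class FixtureTruth:
    """Ground truth emitted alongside a generated corpus."""

    term_freqs: Dict[str, Dict[str, int]]  # lemma_key -> segment -> realized freq
    expected_labels: Dict[str, str]  # lemma_key -> planned lexicon label
    dominant_term: str | None  # highest planted frequency, rank-1 contender

    def total_freq(self, lemma_key: str) -> int:
        return sum(self.term_freqs.get(lemma_key, {}).values())


def example_spec(seed: int = 0) -> FixtureSpec:
    """The standard study conditions used by the examples and checks.

    One dominant in-lexicon term, one lexicon-variant term, one novel
    term (all planted in all three segments), plus a content-only
    insertion variant of the dominant term for driven extraction to
    recover.
    """
    return FixtureSpec(
        n_docs=16,
        vocab_size=200,
        seed=seed,
        planted_terms=(
            PlantedTerm(("influenza", "virus"), freq=80, lexicon_plan=IN),
            PlantedTerm(("health", "emergency"), freq=30, lexicon_plan=VARIANT),
            PlantedTerm(("close", "contact"), freq=24, lexicon_plan=NOT_IN),
            # insertion variant of the dominant term; its bag contains the
            # "influenza virus" lexicon entry, hence the VARIANT plan
            PlantedTerm(
                ("influenza", "pandemic", "virus"),
                freq=6,
                segments=(Segment.CONTENT.value,),
                lexicon_plan=VARIANT,
            ),
        ),
    )


def _filler_vocab(spec: FixtureSpec) -> List[str]:
    planted = {lemma for term in spec.planted_terms for lemma in term.lemmas}
    vocab = [w for w in _BASE_NOUNS if w not in planted]
    i = 0
    while len(vocab) < spec.vocab_size:
        word = f"marker{i}"
        if word not in planted:
            vocab.append(word)
        i += 1
    return vocab[: spec.vocab_size]


def generate_corpus(spec: FixtureSpec) -> Tuple[List[Document], FixtureTruth]:
    """Build the documents and the matching ground truth (see module docs).

    Raises ``ValueError`` naming the term if a planted frequency cannot
    be realized (the per-document share of planted tokens would exceed
    the segment's base document length).
    """
    if spec.n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    for term in spec.planted_terms:
        if term.freq < 0:
            raise ValueError(f"negative frequency for planted term {term.lemma_key!r}")
        for segment in term.segments:
            base_len = spec.segment_length(segment)
            per_doc = ceil(term.freq / spec.n_docs) if term.freq else 0
            if per_doc * len(term.lemmas) > base_len:
                raise ValueError(
                    f"unachievable plan for term {term.lemma_key!r}: "
                    f"{per_doc} occurrence(s)/doc exceeds {segment} length {base_len}"
                )

    rng = random.Random(spec.seed)
    vocab = _filler_vocab(spec)
    fields: Dict[str, List[List[str]]] = {}
    for segment in ALL_SEGMENTS:
        base_len = spec.segment_length(segment)
        # documents are built as lists of atomic units (a filler word or a
        # whole planted term), so a later insertion can never split an
        # earlier planted occurrence and realized frequencies recount exactly
        docs_units: List[List[Tuple[str, ...]]] = [
            [(vocab[rng.randrange(len(vocab))],) for _ in range(base_len)]
            for _ in range(spec.n_docs)
        ]
        for term in spec.planted_terms:
            if segment not in term.segments:
                continue
            share, extra = divmod(term.freq, spec.n_docs)
            for doc_idx in range(spec.n_docs):
                for _ in range(share + (1 if doc_idx < extra else 0)):
                    slot = rng.randrange(len(docs_units[doc_idx]) + 1)
                    docs_units[doc_idx].insert(slot, term.lemmas)
        fields[segment] = [
            [token for unit in units for token in unit] for units in docs_units
        ]

    documents = [
        Document(
            doc_id=f"doc{idx:04d}",
            title=" ".join(fields["title"][idx]),
            abstract=" ".join(fields["abstract"][idx]),
            content=" ".join(fields["content"][idx]),
        )
        for idx in range(spec.n_docs)
    ]

    term_freqs = {
        term.lemma_key: {segment: term.freq for segment in term.segments}
        for term in spec.planted_terms
    }
    dominant = max(spec.planted_terms, key=lambda t: t.freq, default=None)
    truth = FixtureTruth(
        term_freqs=term_freqs,
        expected_labels={t.lemma_key: t.lexicon_plan for t in spec.planted_terms},
        dominant_term=dominant.lemma_key if dominant else None,
    )
    return documents, truth


# entries padding the toy lexicon beyond the planted terms
_DISTRACTOR_ENTRIES = (
    "zymogen cascade",
    "cascade activation unit",
    "quorum sensing relay",
    "osmotic gradient pump",
    "chelation damper",
)

_VARIANT_PAD_WORD = "service"


def generate_lexicon(spec: FixtureSpec) -> List[str]:
    """Toy lexicon entries realizing each planted term's lexicon plan.

    VARIANT-planned terms get a longer entry with the term's words
    reordered plus one pad word, so bag-containment (not substring)
    matching is required to recover them.  The result is validated: if
    any planted term would not categorize as planned (e.g. two plans
    collide through shared words), a ``ValueError`` names the term.
    """
    entries: List[str] = []
    for term in spec.planted_terms:
        if term.lexicon_plan == IN:
            entries.append(" ".join(term.lemmas))
        elif term.lexicon_plan == VARIANT:
            entries.append(" ".join(reversed(term.lemmas)) + " " + _VARIANT_PAD_WORD)
        elif term.lexicon_plan != NOT_IN:
            raise ValueError(f"unknown lexicon plan {term.lexicon_plan!r} for {term.lemma_key!r}")
    entries.extend(_DISTRACTOR_ENTRIES)

    lexicon = ReferenceLexicon.from_terms(entries)
    for term in spec.planted_terms:
        got = categorize_term(term.lemma_key, lexicon).label
        if got != term.lexicon_plan:
            raise ValueError(
                f"lexicon plan for {term.lemma_key!r} not realizable: planned "
                f"{term.lexicon_plan}, categorizes as {got}"
            )
    return entries


def write_lexicon(entries: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(entries) + "\n", encoding="utf-8")
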