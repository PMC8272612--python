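"""Categorizing extracted terms against a reference terminology.

Each term receives one of three labels, mirroring how extracted terms are
audited against a large domain thesaurus such as the UMLS Metathesaurus:

* ``IN`` — the normalized term matches a lexicon entry exactly;
* ``VARIANT`` — no exact match, but the term's content-lemma bag is
  contained in some entry's bag, or vice versa ("health emergency" is a
  variant of the entry "emergency health services": bag containment is
  order-insensitive precisely so reordered sub-terms still match);
* ``NOT_IN`` — neither; the term is a candidate *new* terminology.

Normalization (lowercase, hyphen split, punctuation strip, lemmatize,
drop function words) is shared with candidate extraction so the same
string keys flow through measures, combination sets and this module.
A single-word term can be VARIANT only by being contained in a
multi-word entry — letting unigrams match via *containing* an entry
would inflate the VARIANT class with every word of every entry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Tuple

from ._stopwords import STOP_WORDS
from .tagging import singularize

IN = "IN"
VARIANT = "VARIANT"
NOT_IN = "NOT_IN"
LABELS = (IN, VARIANT, NOT_IN)

_TOKEN_RE = re.compile(r"[a-z0-9']+")


def normalize_term(term: str) -> Tuple[str, ...]:
    """Content-lemma tuple for a raw term string."""
    lemmas = []
    for token in _TOKEN_RE.findall(term.lower().replace("-", " ")):
        if token in STOP_WORDS:
            continue
        lemmas.append(singularize(token))
    return tuple(lemmas)


@dataclass(frozen=True)
class LexiconEntry:
    raw: str
    normalized: Tuple[str, ...]
    entry_id: str = ""

    @property
    def bag(self) -> FrozenSet[str]:
        return frozenset(self.normalized)


@dataclass
class ReferenceLexicon:
    """A flat reference terminology with exact and bag-containment lookup."""

    entries: List[LexiconEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("reference lexicon is empty")
        self.normalized_terms: Dict[Tuple[str, ...], LexiconEntry] = {}
        self._by_lemma: Dict[str, List[LexiconEntry]] = {}
        for entry in self.entries:
            self.normalized_terms.setdefault(entry.normalized, entry)
            for lemma in entry.bag:
                self._by_lemma.setdefault(lemma, []).append(entry)

    def __len__(self) -> int:
        return len(self.normalized_terms)

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in self.normalized_terms

    @classmethod
    def from_terms(cls, terms: Iterable[str]) -> "ReferenceLexicon":
        entries = []
        seen: set[Tuple[str, ...]] = set()
        for raw in terms:
            raw = raw.strip()
            if not raw:
                continue
            entry_id = ""
            if "\t" in raw:  # optional 2-column TSV: id <tab> term
                entry_id, raw = raw.split("\t", 1)
            norm = normalize_term(raw)
            if not norm or norm in seen:
                continue
            seen.add(norm)
            entries.append(LexiconEntry(raw=raw, normalized=norm, entry_id=entry_id))
        return cls(entries=entries)

    def candidates_sharing(self, lemmas: Iterable[str]) -> List[LexiconEntry]:
        seen: set[int] = set()
        out: List[LexiconEntry] = []
        for lemma in lemmas:
            for entry in self._by_lemma.get(lemma, ()):
                if id(entry) not in seen:
                    seen.add(id(entry))
                    out.append(entry)
        return out


def load_lexicon(path: str | Path) -> ReferenceLexicon:
    """One term per line (UTF-8), or 2-column TSV ``id<TAB>term``."""
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        lexicon = ReferenceLexicon.from_terms(handle)
    return lexicon


@dataclass(frozen=True)
class LexiconCategory:
    label: str
    matched_entry: LexiconEntry | None = None

    def __post_init__(self) -> None:
        if (self.matched_entry is not None) != (self.label != NOT_IN):
            raise ValueError("matched_entry present iff label is IN or VARIANT")


def categorize_term(term: str, lexicon: ReferenceLexicon) -> LexiconCategory:
    """IN / VARIANT / NOT_IN trichotomy for one term (precedence IN first)."""
    norm = normalize_term(term)
    if not norm:
        raise ValueError(f"term normalizes to nothing: {term!r}")
    exact = lexicon.normalized_terms.get(norm)
    if exact is not None:
        return LexiconCategory(label=IN, matched_entry=exact)
    bag = frozenset(norm)
    for entry in lexicon.candidates_sharing(bag):
        if bag <= entry.bag and len(entry.normalized) > len(norm):
            return LexiconCategory(label=VARIANT, matched_entry=entry)
        if len(norm) > 1 and entry.bag <= bag and len(entry.normalized) < len(norm):
            return LexiconCategory(label=VARIANT, matched_entry=entry)
    return LexiconCategory(label=NOT_IN)


@dataclass(frozen=True)
class CategoryReport:
    """Per-term labels with counts and percentages over a top-K list."""

    labels: Tuple[Tuple[str, LexiconCategory], ...]
    counts: Mapping[str, int]
    percentages: Mapping[str, float]

    def __len__(self) -> int:
        return len(self.labels)


def categorize_list(
    terms: Sequence[str], lexicon: ReferenceLexicon, k: int | None = None
) -> CategoryReport:
    """Label the top-K of a term list; percentages sum to 100 (float)."""
    if k is not None:
        if k > len(terms):
            raise ValueError(f"k={k} exceeds list length {len(terms)}")
        terms = terms[:k]
    labels = tuple((t, categorize_term(t, lexicon)) for t in terms)
    counts = {label: 0 for label in LABELS}
    for _, cat in labels:
        counts[cat.label] += 1
    n = len(labels)
    percentages = {label: (100.0 * counts[label] / n if n else 0.0) for label in LABELS}
    return CategoryReport(labels=labels, counts=counts, percentages=percentages)


def round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
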