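"""POS-pattern candidate-term extraction.

Every token window of 1-4 words whose tag sequence matches a configured
pattern becomes a candidate term.  Nested windows are emitted as
first-class candidates alongside the maximal ones ("virus" and
"influenza virus" both appear): the C-Value measure's nested correction
is undefined without them.  Occurrences are grouped case-insensitively by
their lemma sequence, with per-document frequencies accumulated for the
TF-IDF computation.

Pattern files use a compressed symbol alphabet: ``NN`` covers singular and
plural common nouns, ``NP`` proper nouns, ``JJ`` all adjective grades and
``RB`` all adverb grades; any other symbol (``VBD``, ``IN``, ...) matches
its exact Penn tag.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

from .tagging import PENN_TAGS, TaggedToken

logger = logging.getLogger(__name__)

MAX_PATTERN_LENGTH = 4

#: Compressed pattern symbols and the Penn tags each one matches.
SYMBOL_CLASSES: Dict[str, frozenset[str]] = {
    "NN": frozenset({"NN", "NNS"}),
    "NP": frozenset({"NNP", "NNPS"}),
    "JJ": frozenset({"JJ", "JJR", "JJS"}),
    "RB": frozenset({"RB", "RBR", "RBS"}),
}


def symbol_matches(symbol: str, tag: str) -> bool:
    return tag in SYMBOL_CLASSES.get(symbol, frozenset({symbol}))


@dataclass(frozen=True)
class PosPattern:
    """A 1-4 symbol tag sequence; priority is its 1-based file position."""

    tags: Tuple[str, ...]
    priority: int

    def __post_init__(self) -> None:
        if not 1 <= len(self.tags) <= MAX_PATTERN_LENGTH:
            raise ValueError(f"pattern length must be 1..{MAX_PATTERN_LENGTH}: {' '.join(self.tags)}")
        for symbol in self.tags:
            if symbol not in SYMBOL_CLASSES and symbol not in PENN_TAGS:
                raise ValueError(f"unknown tag symbol {symbol!r} in pattern {' '.join(self.tags)}")

    def __len__(self) -> int:
        return len(self.tags)

    def matches(self, tags: Sequence[str]) -> bool:
        return len(tags) == len(self.tags) and all(
            symbol_matches(s, t) for s, t in zip(self.tags, tags)
        )

    def __str__(self) -> str:
        return " ".join(self.tags)


@dataclass
class CandidateTerm:
    """A candidate grouped by lemma sequence with its corpus statistics.

    ``freq`` is the total corpus frequency f(a); ``per_doc_tf`` maps
    doc_id to the occurrence count in that document, so
    ``freq == sum(per_doc_tf.values())`` and ``doc_freq == len(per_doc_tf)``.
    """

    lemma_key: str
    surface: str
    length: int
    pattern: PosPattern
    freq: int
    doc_freq: int
    per_doc_tf: Dict[str, int]

    @property
    def lemmas(self) -> Tuple[str, ...]:
        return tuple(self.lemma_key.split(" "))


def parse_patterns(lines: Iterable[str], source: str = "<patterns>") -> List[PosPattern]:
    patterns: List[PosPattern] = []
    for line_no, line in enumerate(lines, start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        tags = tuple(body.split())
        if len(tags) > MAX_PATTERN_LENGTH:
            raise ValueError(f"{source} line {line_no}: pattern longer than {MAX_PATTERN_LENGTH} tags: {body!r}")
        patterns.append(PosPattern(tags=tags, priority=len(patterns) + 1))
    return patterns


def load_patterns(path: str | Path) -> List[PosPattern]:
    """Read one space-separated pattern per line; ``#`` starts a comment."""
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        return parse_patterns(handle, source=str(path))


def default_patterns() -> List[PosPattern]:
    """The shipped 50-pattern file (user-replaceable via ``load_patterns``)."""
    text = resources.files("bioterm").joinpath("data/patterns_default.txt").read_text("utf-8")
    return parse_patterns(text.splitlines(), source="patterns_default.txt")


def extract_candidates(
    tagged_docs: Sequence[Tuple[str, Sequence[TaggedToken]]],
    patterns: Sequence[PosPattern],
    ngram_min: int = 1,
    ngram_max: int = MAX_PATTERN_LENGTH,
) -> List[CandidateTerm]:
    """Emit every (nested or maximal) pattern-matching window as a candidate.

    Windows never cross sentence boundaries.  When several patterns match
    one window the highest-priority (earliest) pattern is recorded.
    Returns candidates sorted by descending frequency then lemma_key.
    """
    if not patterns:
        raise ValueError("at least one pattern is required")
    by_length: Dict[int, List[PosPattern]] = defaultdict(list)
    for pat in patterns:
        if ngram_min <= len(pat) <= ngram_max:
            by_length[len(pat)].append(pat)

    groups: Dict[Tuple[str, ...], dict] = {}
    for doc_id, tokens in tagged_docs:
        for window, pattern in _matching_windows(tokens, by_length):
            lemmas = tuple(t.lemma for t in window)
            surface = " ".join(t.surface for t in window)
            group = groups.get(lemmas)
            if group is None:
                group = groups[lemmas] = {
                    "surfaces": Counter(),
                    "pattern": pattern,
                    "per_doc": Counter(),
                }
            group["surfaces"][surface] += 1
            group["per_doc"][doc_id] += 1
            if pattern.priority < group["pattern"].priority:
                group["pattern"] = pattern

    candidates: List[CandidateTerm] = []
    for lemmas, group in groups.items():
        per_doc = dict(group["per_doc"])
        freq = sum(per_doc.values())
        # modal surface realization; ties broken lexicographically
        surface = min(group["surfaces"].items(), key=lambda kv: (-kv[1], kv[0]))[0]
        candidates.append(
            CandidateTerm(
                lemma_key=" ".join(lemmas),
                surface=surface,
                length=len(lemmas),
                pattern=group["pattern"],
                freq=freq,
                doc_freq=len(per_doc),
                per_doc_tf=per_doc,
            )
        )
    candidates.sort(key=lambda c: (-c.freq, c.lemma_key))
    logger.info("extracted %d candidate term(s) from %d document(s)", len(candidates), len(tagged_docs))
    return candidates


def _matching_windows(
    tokens: Sequence[TaggedToken], by_length: Dict[int, List[PosPattern]]
):
    n = len(tokens)
    for start in range(n):
        for length, pats in by_length.items():
            end = start + length
            if end > n:
                continue
            window = tokens[start:end]
            if window[-1].sentence != window[0].sentence:
                continue
            tags = [t.tag for t in window]
            for pat in pats:
                if pat.matches(tags):
                    yield window, pat
                    break


def split_by_length(
    candidates: Iterable[CandidateTerm],
) -> Tuple[List[CandidateTerm], List[CandidateTerm]]:
    """Partition into single-word terms (SWT) and multi-word terms (MWT)."""
    swt = [c for c in candidates if c.length == 1]
    mwt = [c for c in candidates if c.length >= 2]
    return swt, mwt


def write_candidates_tsv(candidates: Iterable[CandidateTerm], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("lemma_key\tsurface\tlength\tpattern\tfreq\tdoc_freq\n")
        for c in candidates:
            handle.write(f"{c.lemma_key}\t{c.surface}\t{c.length}\t{c.pattern}\t{c.freq}\t{c.doc_freq}\n")
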