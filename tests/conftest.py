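"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive results from first principles
(window enumeration, direct formula evaluation) without touching the
implementation paths they check.
"""

from __future__ import annotations

import math
import random
from typing import Dict, List, Sequence, Tuple

import pytest

from bioterm.extraction import CandidateTerm, PosPattern, symbol_matches
from bioterm.synthetic import example_spec, generate_corpus, generate_lexicon
from bioterm.tagging import TaggedToken


# --- oracles ----------------------------------------------------------------


def brute_force_windows(
    tagged_docs: Sequence[Tuple[str, Sequence[TaggedToken]]],
    patterns: Sequence[PosPattern],
    ngram_min: int = 1,
    ngram_max: int = 4,
) -> Dict[Tuple[str, ...], Dict[str, int]]:
    """Enumerate every matching window; lemma tuple -> doc_id -> count."""
    counts: Dict[Tuple[str, ...], Dict[str, int]] = {}
    for doc_id, tokens in tagged_docs:
        for start in range(len(tokens)):
            for length in range(ngram_min, ngram_max + 1):
                window = tokens[start : start + length]
                if len(window) < length:
                    continue
                if any(t.sentence != window[0].sentence for t in window):
                    continue
                if any(
                    len(p) == length
                    and all(symbol_matches(s, t.tag) for s, t in zip(p.tags, window))
                    for p in patterns
                ):
                    key = tuple(t.lemma for t in window)
                    counts.setdefault(key, {}).setdefault(doc_id, 0)
                    counts[key][doc_id] += 1
    return counts


def direct_c_value(
    lemmas: Tuple[str, ...], freqs: Dict[Tuple[str, ...], int]
) -> float:
    """Direct evaluation of the nested-correction formula over a frequency
    table: containers found by substring scan, no shared code with the
    implementation."""
    containers = [
        other
        for other in freqs
        if len(other) > len(lemmas)
        and any(other[i : i + len(lemmas)] == lemmas for i in range(len(other) - len(lemmas) + 1))
    ]
    weight = math.log2(len(lemmas) + 1)
    if not containers:
        score = weight * freqs[lemmas]
    else:
        score = weight * (freqs[lemmas] - sum(freqs[c] for c in containers) / len(containers))
    return max(score, 0.0)


def make_candidate(
    lemmas: Tuple[str, ...], per_doc: Dict[str, int], pattern_len: int | None = None
) -> CandidateTerm:
    pattern = PosPattern(tags=("NN",) * (pattern_len or len(lemmas)), priority=1)
    return CandidateTerm(
        lemma_key=" ".join(lemmas),
        surface=" ".join(lemmas),
        length=len(lemmas),
        pattern=pattern,
        freq=sum(per_doc.values()),
        doc_freq=len(per_doc),
        per_doc_tf=dict(per_doc),
    )


def random_candidate_table(
    rng: random.Random, n_max: int = 50, alphabet: str = "abcdef"
) -> List[CandidateTerm]:
    """A random internally-consistent candidate set over a tiny alphabet,
    dense enough that nesting relations actually occur."""
    n = rng.randint(2, n_max)
    seen: dict[Tuple[str, ...], Dict[str, int]] = {}
    while len(seen) < n:
        length = rng.randint(1, 4)
        lemmas = tuple(rng.choice(alphabet) for _ in range(length))
        if lemmas in seen:
            continue
        n_docs = rng.randint(1, 4)
        seen[lemmas] = {f"d{i}": rng.randint(1, 9) for i in range(n_docs)}
    return [make_candidate(lemmas, per_doc) for lemmas, per_doc in seen.items()]


# --- fixtures ---------------------------------------------------------------


@pytest.fixture(scope="session")
def fixture_corpus():
    """The example synthetic corpus with its ground truth and lexicon."""
    spec = example_spec(seed=7)
    docs, truth = generate_corpus(spec)
    lexicon_entries = generate_lexicon(spec)
    return spec, docs, truth, lexicon_entries


@pytest.fixture()
def rng():
    return random.Random(20240917)
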