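"""Tokenization, lemmatization and Penn-Treebank POS tagging.

The extraction pipeline is tagger-agnostic: any callable mapping raw text
to a list of :class:`TaggedToken` can be injected wherever a ``tagger``
argument appears.  The built-in :class:`RuleTagger` is a deterministic
suffix/lexicon tagger that needs no model download, which keeps the whole
toolkit reproducible offline; for production corpora a statistical tagger
exposing the Penn tagset can be dropped in unchanged.

Tokens are split on whitespace, punctuation and hyphens (hyphenated
compounds such as ``coronavirus-related`` become two tokens, so phrase
matching sees their parts).  Sentence boundaries are detected on
``. ! ? ;`` and blank lines; candidate and variant windows never cross
them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Callable, Iterable, List, Protocol

from ._stopwords import STOP_WORDS

logger = logging.getLogger(__name__)

#: The Penn Treebank word-level tag inventory.
PENN_TAGS: frozenset[str] = frozenset(
    """
    CC CD DT EX FW IN JJ JJR JJS LS MD NN NNS NNP NNPS PDT POS PRP PRP$
    RB RBR RBS RP SYM TO UH VB VBD VBG VBN VBP VBZ WDT WP WP$ WRB
    """.split()
)

#: Catch-all for injected taggers emitting tags outside the inventory.
CATCH_ALL_TAG = "FW"


@dataclass(frozen=True)
class TaggedToken:
    """One token with its surface form, lowercased lemma and Penn tag.

    ``position`` is the 0-based token index within the document;
    ``sentence`` indexes the sentence the token belongs to, so that
    window-based matching can stay intra-sentential.
    """

    surface: str
    lemma: str
    tag: str
    position: int
    sentence: int = 0

    @property
    def is_stop(self) -> bool:
        return self.lemma in STOP_WORDS or self.surface.lower() in STOP_WORDS


class Tagger(Protocol):
    def __call__(self, text: str) -> List[TaggedToken]: ...


# --- lemmatization ----------------------------------------------------------

_IRREGULAR_PLURALS = {
    "viruses": "virus",
    "mice": "mouse",
    "men": "man",
    "women": "woman",
    "children": "child",
    "feet": "foot",
    "teeth": "tooth",
    "people": "person",
    "analyses": "analysis",
    "diagnoses": "diagnosis",
    "hypotheses": "hypothesis",
    "crises": "crisis",
    "bases": "basis",
    "criteria": "criterion",
    "bacteria": "bacterium",
    "media": "medium",
    "phenomena": "phenomenon",
    "fungi": "fungus",
    "nuclei": "nucleus",
    "foci": "focus",
    "genera": "genus",
    "indices": "index",
    "matrices": "matrix",
    "vertices": "vertex",
    "appendices": "appendix",
}

# Words these suffix rules must not singularize.
_SINGULAR_S = ("ss", "us", "is", "ics")


def singularize(word: str) -> str:
    """Rule-based noun singularization (lowercase in, lowercase out)."""
    if word in _IRREGULAR_PLURALS:
        return _IRREGULAR_PLURALS[word]
    if len(word) < 4 or not word.endswith("s"):
        return word
    if word.endswith(_SINGULAR_S):
        return word
    if word.endswith("ies"):
        return word[:-3] + "y"
    if word.endswith(("sses", "xes", "zes", "ches", "shes")):
        return word[:-2]
    return word[:-1]


def lemmatize_word(word: str, tag: str = "NN") -> str:
    """Lowercased lemma for one token given its Penn tag.

    Only inflectional morphology is handled (plural nouns, a crude verb
    form strip); derivational variants are out of scope.
    """
    low = word.lower()
    if tag in ("NNS", "NNPS"):
        return singularize(low)
    if tag in ("VBG",) and low.endswith("ing") and len(low) > 5:
        return low[:-3]
    if tag in ("VBD", "VBN") and low.endswith("ed") and len(low) > 4:
        return low[:-2]
    if tag in ("NN", "NNP") and low in _IRREGULAR_PLURALS:
        # tagger may miss irregular plurals; normalize anyway
        return _IRREGULAR_PLURALS[low]
    return low


# --- the built-in rule tagger -----------------------------------------------

_WORD_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9']*")
_SENT_SPLIT_RE = re.compile(r"[.!?;]+|\n\s*\n")
_NUM_RE = re.compile(r"^\d+([.,]\d+)?$")

_CLOSED_CLASS = {
    **{w: "DT" for w in ("the", "a", "an", "this", "that", "these", "those")},
    **{
        w: "IN"
        for w in (
            "of in on at by for with from as into onto over under between "
            "among within without about against after before above below "
            "per via than during until if because while where"
        ).split()
    },
    "to": "TO",
    **{w: "CC" for w in ("and", "or", "but", "nor")},
    **{w: "PRP" for w in "i you he she it we they them us him me".split()},
    **{w: "PRP$" for w in "my your his her its our their".split()},
    **{w: "MD" for w in "can will shall may might must should would could".split()},
    "is": "VBZ",
    "are": "VBP",
    "was": "VBD",
    "were": "VBD",
    "be": "VB",
    "been": "VBN",
    "being": "VBG",
    "has": "VBZ",
    "have": "VBP",
    "had": "VBD",
    "do": "VBP",
    "does": "VBZ",
    "did": "VBD",
    "not": "RB",
    "no": "DT",
    "there": "EX",
    "which": "WDT",
    "who": "WP",
    "whose": "WP$",
    "when": "WRB",
    "how": "WRB",
    "why": "WRB",
    "including": "VBG",
}

# frequent words the suffix rules would mistag
_LEXICAL_OVERRIDES = {
    "higher": "JJR",
    "lower": "JJR",
    "greater": "JJR",
    "larger": "JJR",
    "smaller": "JJR",
    "highest": "JJS",
    "lowest": "JJS",
    "new": "JJ",
    "novel": "JJ",
    "human": "JJ",
    "severe": "JJ",
    "early": "JJ",
    "late": "JJ",
    "acute": "JJ",
    "public": "JJ",
    "viral": "JJ",
    "respiratory": "JJ",
    "infectious": "JJ",
    "animal": "NN",
    "hospital": "NN",
    "trial": "NN",
    "material": "NN",
    "interval": "NN",
    "individual": "NN",
    "control": "NN",
    "protocol": "NN",
    "level": "NN",
    "model": "NN",
    "panel": "NN",
    "signal": "NN",
    "channel": "NN",
    "potential": "NN",
    "setting": "NN",
    "finding": "NN",
    "building": "NN",
    "screening": "NN",
    "morning": "NN",
    "evening": "NN",
}

_ADJ_SUFFIXES = (
    "ous", "ful", "ive", "ic", "ical", "al", "ary", "ory",
    "able", "ible", "ish", "less", "ant", "ent",
)


class RuleTagger:
    """Deterministic suffix/lexicon Penn tagger for English.

    Accuracy is intentionally traded for determinism: closed-class words
    come from a lexicon, numbers tag CD, adjectives and verb participles
    are recognized by suffix, capitalized non-initial tokens tag as proper
    nouns, and everything else defaults to noun (singular or plural).
    """

    def __call__(self, text: str) -> List[TaggedToken]:
        tokens: List[TaggedToken] = []
        if not text or not text.strip():
            return tokens
        position = 0
        # hyphens separate tokens so compound parts are visible to matching
        for sent_idx, sentence in enumerate(s for s in _SENT_SPLIT_RE.split(text) if s.strip()):
            for tok_idx, match in enumerate(_WORD_RE.finditer(sentence.replace("-", " "))):
                surface = match.group(0)
                tag = self._tag_one(surface, first_in_sentence=(tok_idx == 0))
                lemma = lemmatize_word(surface, tag)
                tokens.append(TaggedToken(surface, lemma, tag, position, sent_idx))
                position += 1
        return tokens

    @staticmethod
    def _tag_one(surface: str, first_in_sentence: bool) -> str:
        low = surface.lower()
        if low in _CLOSED_CLASS:
            return _CLOSED_CLASS[low]
        if _NUM_RE.match(surface):
            return "CD"
        if low in _LEXICAL_OVERRIDES:
            return _LEXICAL_OVERRIDES[low]
        if surface[0].isupper() and not first_in_sentence:
            return "NNPS" if low.endswith("s") and not low.endswith(_SINGULAR_S) else "NNP"
        if low.endswith("ly") and len(low) > 4:
            return "RB"
        if low.endswith("ing") and len(low) > 5:
            return "VBG"
        if low.endswith("ed") and len(low) > 4:
            return "VBD"
        for suffix in _ADJ_SUFFIXES:
            if low.endswith(suffix) and len(low) > len(suffix) + 2:
                return "JJ"
        if low.endswith("s") and not low.endswith(_SINGULAR_S) and len(low) > 3:
            return "NNS"
        return "NN"


_DEFAULT_TAGGER = RuleTagger()


def tag_document(text: str, tagger: Tagger | None = None) -> List[TaggedToken]:
    """Tag one document, validating the tagger's output tags.

    Tokens carrying a tag outside the Penn inventory are kept but remapped
    to a catch-all class (with a logged warning) so that downstream pattern
    matching only ever sees known symbols.
    """
    tokens = (tagger or _DEFAULT_TAGGER)(text)
    checked: List[TaggedToken] = []
    for tok in tokens:
        if tok.tag not in PENN_TAGS:
            logger.warning("non-Penn tag %r on token %r mapped to %s", tok.tag, tok.surface, CATCH_ALL_TAG)
            tok = TaggedToken(tok.surface, tok.lemma, CATCH_ALL_TAG, tok.position, tok.sentence)
        checked.append(tok)
    return checked


def tag_corpus(
    documents: Iterable[tuple[str, str]], tagger: Tagger | None = None
) -> List[tuple[str, List[TaggedToken]]]:
    """Tag ``(doc_id, text)`` pairs, preserving order."""
    return [(doc_id, tag_document(text, tagger)) for doc_id, text in documents]
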