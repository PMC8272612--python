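"""Intra- and inter-corpus set-combination strategies.

Two complementary comparisons turn ranked term lists into representative,
discriminant and common term sets:

* **Intra-corpus** — one corpus, two measures.  The top-K lists of
  C-Value and F-TFIDF-C are compared: terms found by only one measure
  are *discriminant* for that measure (sets A and B); the intersection C
  holds the corpus's most *representative* terms.

* **Inter-corpus** — one measure, three segments (title / abstract /
  content).  Pairwise intersections Set(TA) = T ∩ A and Set(TC) = T ∩ C
  show how far title terms persist into the longer segments; the
  three-way intersection D holds corpus-wide *common* terms; terms found
  in exactly one segment are that segment's discriminants.

Either kind of set can then drive variant extraction (seeding the driven
process with the common set is the default, those terms being the most
representative).  Set membership uses the shared lemma-key normalization,
so the same term string compares equal across measures and segments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .corpus import Segment
from .lexicon import LexiconCategory, ReferenceLexicon, categorize_term, round_half_up
from .measures import C_VALUE, F_TFIDF_C_M, RankedTermList
from .variants import SeedTerm

logger = logging.getLogger(__name__)

COMMON = "common"
DISCRIMINANT = "discriminant"


@dataclass(frozen=True)
class IntraCorpusReport:
    """Measure comparison on one corpus: A (C-Value only), B (F-TFIDF-C
    only), C (both = representative)."""

    corpus_label: str
    k: int
    only_c_value: frozenset[str]
    only_f_tfidf: frozenset[str]
    common: frozenset[str]
    lexicon_annotation: Mapping[str, LexiconCategory] | None = None

    @property
    def all_terms(self) -> frozenset[str]:
        return self.only_c_value | self.only_f_tfidf | self.common


@dataclass(frozen=True)
class InterCorpusReport:
    """Segment comparison for one measure with the five sets
    Set(T), Set(A), Set(C), Set(TA), Set(TC) plus D and discriminants."""

    measure: str
    k: int
    segment_sets: Mapping[str, frozenset[str]]  # segment label -> top-K set
    set_ta: frozenset[str]
    set_tc: frozenset[str]
    common: frozenset[str]  # D: in all three segments
    discriminants: Mapping[str, frozenset[str]]  # per-segment exclusives


def _top_set(ranked: RankedTermList, k: int) -> frozenset[str]:
    if len(ranked) < k:
        raise ValueError(
            f"list for {ranked.source or ranked.measure} has {len(ranked)} terms, need top-{k}"
        )
    return frozenset(ranked.terms(k))


def intra_corpus_combination(
    list_cv: RankedTermList,
    list_ft: RankedTermList,
    lexicon: Optional[ReferenceLexicon] = None,
    k: int = 100,
) -> IntraCorpusReport:
    """Compare the two measures' top-K lists from one corpus."""
    if list_cv.source != list_ft.source:
        raise ValueError(
            f"corpus label mismatch: {list_cv.source!r} vs {list_ft.source!r}"
        )
    if list_cv.measure != C_VALUE or list_ft.measure != F_TFIDF_C_M:
        raise ValueError("expected a C_VALUE list and an F_TFIDF_C_M list, in that order")
    top_cv = _top_set(list_cv, k)
    top_ft = _top_set(list_ft, k)
    annotation = None
    if lexicon is not None:
        annotation = {t: categorize_term(t, lexicon) for t in top_cv | top_ft}
    return IntraCorpusReport(
        corpus_label=list_cv.source,
        k=k,
        only_c_value=frozenset(top_cv - top_ft),
        only_f_tfidf=frozenset(top_ft - top_cv),
        common=frozenset(top_cv & top_ft),
        lexicon_annotation=annotation,
    )


def inter_corpus_combination(
    per_segment: Mapping[str, RankedTermList] | Sequence[RankedTermList],
    k: int = 100,
) -> InterCorpusReport:
    """Compare one measure's top-K lists across title/abstract/content."""
    if not isinstance(per_segment, Mapping):
        per_segment = {lst.source: lst for lst in per_segment}
    labels = [Segment.TITLE.value, Segment.ABSTRACT.value, Segment.CONTENT.value]
    missing = [s for s in labels if s not in per_segment]
    if missing:
        raise ValueError(f"missing ranked list(s) for segment(s): {missing}")
    measures = {lst.measure for lst in per_segment.values()}
    if len(measures) > 1:
        raise ValueError(f"measure mismatch across segments: {sorted(measures)}")
    sets = {label: _top_set(per_segment[label], k) for label in labels}
    t, a, c = (sets[label] for label in labels)
    return InterCorpusReport(
        measure=next(iter(measures)),
        k=k,
        segment_sets=sets,
        set_ta=frozenset(t & a),
        set_tc=frozenset(t & c),
        common=frozenset(t & a & c),
        discriminants={
            labels[0]: frozenset(t - a - c),
            labels[1]: frozenset(a - t - c),
            labels[2]: frozenset(c - t - a),
        },
    )


def overlap_percentages(report: InterCorpusReport) -> Dict[str, Optional[int]]:
    """|TA|/|T|, |TC|/|T| and |D|/|T| as integer percentages (half-up).

    Undefined (None) when the title set is empty.
    """
    t = report.segment_sets[Segment.TITLE.value]
    if not t:
        logger.warning("empty title set: overlap percentages undefined")
        return {"title_in_abstract": None, "title_in_content": None, "common": None}
    n = len(t)
    return {
        "title_in_abstract": round_half_up(100.0 * len(report.set_ta) / n),
        "title_in_content": round_half_up(100.0 * len(report.set_tc) / n),
        "common": round_half_up(100.0 * len(report.common) / n),
    }


def select_driven_seeds(
    report: InterCorpusReport,
    strategy: str = COMMON,
    segment: str | Segment | None = None,
) -> List[SeedTerm]:
    """Turn a combination set into seed terms for driven extraction.

    ``common`` takes the three-way intersection D (the default: those are
    the most representative terms); ``discriminant`` takes one segment's
    exclusive set.
    """
    if strategy == COMMON:
        chosen = report.common
    elif strategy == DISCRIMINANT:
        if segment is None:
            raise ValueError("discriminant strategy requires a segment")
        chosen = report.discriminants[Segment(segment).value]
    else:
        raise ValueError(f"unknown seed-selection strategy {strategy!r}")
    if not chosen:
        logger.warning("seed-selection strategy %r produced no terms", strategy)
    return [SeedTerm.from_string(term) for term in sorted(chosen)]


# --- reporting --------------------------------------------------------------


def intra_report_json(report: IntraCorpusReport) -> Dict:
    out = {
        "corpus": report.corpus_label,
        "k": report.k,
        "only_c_value": sorted(report.only_c_value),
        "only_f_tfidf_c_m": sorted(report.only_f_tfidf),
        "common": sorted(report.common),
    }
    if report.lexicon_annotation is not None:
        out["lexicon"] = {t: cat.label for t, cat in sorted(report.lexicon_annotation.items())}
    return out


def inter_report_json(report: InterCorpusReport) -> Dict:
    return {
        "measure": report.measure,
        "k": report.k,
        "segments": {s: sorted(v) for s, v in report.segment_sets.items()},
        "set_ta": sorted(report.set_ta),
        "set_tc": sorted(report.set_tc),
        "common": sorted(report.common),
        "discriminants": {s: sorted(v) for s, v in report.discriminants.items()},
        "overlap_percentages": overlap_percentages(report),
    }


def write_report(report_dict: Dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report_dict, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")
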