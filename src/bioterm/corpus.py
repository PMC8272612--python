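"""Corpus loading, segmentation and partitioning.

A corpus is a list of :class:`Document` records, each carrying up to three
text fields (title, abstract, content).  Segmentation projects the corpus
onto one field, producing the per-segment sub-corpora the ranking measures
are run on; partitioning chops a (typically large) segmented corpus into
fixed-size chunks whose ranked lists are later recombined by average rank.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

logger = logging.getLogger(__name__)


class Segment(str, Enum):
    """The three document parts a corpus can be projected onto."""

    TITLE = "title"
    ABSTRACT = "abstract"
    CONTENT = "content"


@dataclass(frozen=True)
class Document:
    """One paper-like record; at least one text field must be non-empty."""

    doc_id: str
    title: str = ""
    abstract: str = ""
    content: str = ""

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if not (self.title.strip() or self.abstract.strip() or self.content.strip()):
            raise ValueError(f"document {self.doc_id!r} has no non-empty text field")

    def text_for(self, segment: Segment) -> str:
        return getattr(self, Segment(segment).value)


@dataclass(frozen=True)
class SegmentedCorpus:
    """One segment's view of a corpus: ordered (doc_id, text), empties dropped."""

    segment: Segment
    documents: Tuple[Tuple[str, str], ...]
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def label(self) -> str:
        return self.segment.value


@dataclass(frozen=True)
class Partition:
    """Sequential chunking of a segmented corpus into sub-corpora."""

    chunks: Tuple[SegmentedCorpus, ...]
    chunk_size: int

    def __len__(self) -> int:
        return len(self.chunks)

    def sizes(self) -> List[int]:
        return [len(c) for c in self.chunks]


# --- loading ----------------------------------------------------------------

_JSONL_FIELDS = ("title", "abstract", "content")


def load_corpus(source: str | Path, format: str | None = None) -> List[Document]:
    """Load documents from a JSONL file or a directory of plain-text files.

    JSONL records need a ``doc_id`` key and at least one of ``title`` /
    ``abstract`` / ``content``; invalid records are skipped with a logged
    warning.  In directory mode each ``*.txt`` file becomes one document:
    the filename stem is the doc_id and the file body goes to ``content``.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"corpus source does not exist: {path}")
    if format is None:
        format = "text_dir" if path.is_dir() else "jsonl"
    if format == "jsonl":
        return _load_jsonl(path)
    if format == "text_dir":
        return _load_text_dir(path)
    raise ValueError(f"unknown corpus format: {format!r}")


def _load_jsonl(path: Path) -> List[Document]:
    docs: List[Document] = []
    n_skipped = 0
    with open(path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
                doc = Document(
                    doc_id=str(record.get("doc_id", "") or ""),
                    **{f: str(record.get(f, "") or "") for f in _JSONL_FIELDS},
                )
            except (json.JSONDecodeError, ValueError) as exc:
                n_skipped += 1
                logger.warning("%s line %d skipped: %s", path, line_no, exc)
                continue
            docs.append(doc)
    if n_skipped:
        logger.warning("%s: %d invalid record(s) skipped, %d loaded", path, n_skipped, len(docs))
    _check_unique_ids(docs)
    return docs


def _load_text_dir(path: Path) -> List[Document]:
    docs: List[Document] = []
    for file in sorted(path.glob("*.txt")):
        try:
            text = file.read_text(encoding="utf-8")
        except OSError as exc:
            raise OSError(f"unreadable corpus file {file}: {exc}") from exc
        if text.strip():
            docs.append(Document(doc_id=file.stem, content=text))
        else:
            logger.warning("empty corpus file skipped: %s", file)
    _check_unique_ids(docs)
    return docs


def _check_unique_ids(docs: Sequence[Document]) -> None:
    seen: set[str] = set()
    for doc in docs:
        if doc.doc_id in seen:
            raise ValueError(f"duplicate doc_id in corpus: {doc.doc_id!r}")
        seen.add(doc.doc_id)


def write_corpus_jsonl(docs: Iterable[Document], path: str | Path) -> None:
    """Write documents in the JSONL format ``load_corpus`` reads back."""
    with open(path, "w", encoding="utf-8") as handle:
        for doc in docs:
            handle.write(
                json.dumps(
                    {"doc_id": doc.doc_id, "title": doc.title, "abstract": doc.abstract, "content": doc.content},
                    ensure_ascii=False,
                )
                + "\n"
            )


# --- segmentation and partitioning ------------------------------------------


def segment_corpus(docs: Sequence[Document], segment: Segment | str) -> SegmentedCorpus:
    """Project the corpus onto one text field, dropping empty-field docs."""
    segment = Segment(segment)
    kept: List[Tuple[str, str]] = []
    dropped = 0
    for doc in docs:
        text = doc.text_for(segment)
        if text.strip():
            kept.append((doc.doc_id, text))
        else:
            dropped += 1
    if dropped:
        logger.info("segment %s: dropped %d empty-field document(s)", segment.value, dropped)
    return SegmentedCorpus(segment=segment, documents=tuple(kept), n_dropped=dropped)


def partition_corpus(
    corpus: SegmentedCorpus, chunk_size: int, merge_last: bool = True
) -> Partition:
    """Chunk a segmented corpus sequentially into ``chunk_size``-document pieces.

    With ``merge_last`` (the default) an undersized final remainder is
    merged into the preceding chunk, so 9315 documents at chunk_size 1000
    yield 8 chunks of 1000 plus one of 1315 rather than a trailing chunk
    of 315.
    """
    if chunk_size < 1:
        raise ValueError(f"chunk_size must be >= 1, got {chunk_size}")
    docs = corpus.documents
    bounds = list(range(0, len(docs), chunk_size))
    raw = [docs[i : i + chunk_size] for i in bounds]
    if merge_last and len(raw) >= 2 and len(raw[-1]) < chunk_size:
        raw[-2] = raw[-2] + raw[-1]
        raw.pop()
    chunks = tuple(
        SegmentedCorpus(segment=corpus.segment, documents=tuple(chunk)) for chunk in raw
    )
    return Partition(chunks=chunks, chunk_size=chunk_size)
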