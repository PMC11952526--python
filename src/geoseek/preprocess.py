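"""Document assembly, text cleaning, and overlapping character chunking.

Each series' document is its title, summary, and overall design (when
present) joined with single spaces.  Cleaning applies a fixed rule order —
HTML-tag strip, URL removal, lowercasing, non-alphanumeric replacement,
whitespace collapse, then optional stop-word removal — so that any two runs
over the same input produce identical text.  Non-alphanumeric characters
become spaces rather than being deleted, which keeps hyphenated compounds
("T-cells") as separate words instead of fusing them.  "Alphanumeric" is
decided by Unicode category, so accented names survive cleaning.

Long documents are split into fixed-size character windows with a small
overlap; a document at or below the threshold stays in one piece.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .ingest import SeriesRecord

__all__ = [
    "CleanDocument",
    "ChunkSet",
    "build_document",
    "clean_text",
    "clean_record",
    "chunk_text",
    "chunk_document",
    "load_stopwords",
    "DEFAULT_CHUNK_SIZE",
    "DEFAULT_CHUNK_OVERLAP",
    "DEFAULT_CHUNK_THRESHOLD",
]

DEFAULT_CHUNK_SIZE = 256
DEFAULT_CHUNK_OVERLAP = 20
DEFAULT_CHUNK_THRESHOLD = 256

_TAG_RE = re.compile(r"<[^<>]*>")
_URL_RE = re.compile(r"\b(?:https?|ftp)://\S+|\bwww\.\S+", re.IGNORECASE)


@dataclass(frozen=True)
class CleanDocument:
    """Cleaned text for one series: lowercase alphanumerics and single spaces."""

    accession: str
    text: str

    @property
    def char_count(self) -> int:
        return len(self.text)


@dataclass(frozen=True)
class ChunkSet:
    """Half-open (start, end) character windows into a clean text."""

    accession: str
    chunks: tuple[tuple[int, int], ...]
    overlap: int

    def __iter__(self):
        return iter(self.chunks)

    def __len__(self) -> int:
        return len(self.chunks)


def build_document(record: SeriesRecord) -> str:
    """Join title, summary, and overall design (when available) with spaces."""
    parts = [record.title, record.summary]
    if record.overall_design is not None:
        parts.append(record.overall_design)
    return " ".join(parts)


def clean_text(
    raw: str,
    remove_stopwords: bool = False,
    stopword_list: frozenset[str] | set[str] = frozenset(),
) -> str:
    """Normalize free text to lowercase alphanumeric words.

    Rule order is fixed: strip HTML tags, remove URLs (scheme-prefixed or
    ``www.``-prefixed tokens), lowercase, replace every non-alphanumeric
    character with a space, collapse whitespace, then drop stop words if
    requested.  Idempotent: cleaning already-clean text is a no-op.
    """
    text = _TAG_RE.sub(" ", raw)
    text = _URL_RE.sub(" ", text)
    text = text.lower()
    text = "".join(c if c.isalnum() else " " for c in text)
    tokens = text.split()
    if remove_stopwords:
        tokens = [t for t in tokens if t not in stopword_list]
    return " ".join(tokens)


def clean_record(
    record: SeriesRecord,
    remove_stopwords: bool = False,
    stopword_list: frozenset[str] | set[str] = frozenset(),
) -> CleanDocument:
    """Build and clean one series' document."""
    return CleanDocument(
        accession=record.accession,
        text=clean_text(build_document(record), remove_stopwords, stopword_list),
    )


def chunk_text(
    text: str,
    size: int = DEFAULT_CHUNK_SIZE,
    overlap: int = DEFAULT_CHUNK_OVERLAP,
    threshold: int = DEFAULT_CHUNK_THRESHOLD,
) -> tuple[tuple[int, int], ...]:
    """Split clean text into overlapping (start, end) character windows.

    Text no longer than *threshold* stays whole.  Otherwise windows of
    *size* characters start every ``size - overlap`` characters; the final
    window is truncated at the text end, and generation stops as soon as a
    window reaches the end.
    """
    if overlap >= size:
        raise ValueError(f"overlap ({overlap}) must be smaller than chunk size ({size})")
    n = len(text)
    if n <= threshold:
        return ((0, n),)
    step = size - overlap
    chunks = []
    start = 0
    while True:
        end = min(start + size, n)
        chunks.append((start, end))
        if end >= n:
            return tuple(chunks)
        start += step


def chunk_document(
    doc: CleanDocument,
    size: int = DEFAULT_CHUNK_SIZE,
    overlap: int = DEFAULT_CHUNK_OVERLAP,
    threshold: int = DEFAULT_CHUNK_THRESHOLD,
) -> ChunkSet:
    return ChunkSet(
        accession=doc.accession,
        chunks=chunk_text(doc.text, size, overlap, threshold),
        overlap=overlap,
    )


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Load a stop-word list (one lowercase word per line, UTF-8).

    With no path, loads the English list shipped with the package.
    """
    if path is None:
        text = resources.files("geoseek.data").joinpath("stopwords_en.txt").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    return frozenset(w for w in (line.strip() for line in text.splitlines()) if w)
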