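"""Read supplementary documents into an ordered, page-aware line sequence.

Supplementary-information files arrive either as PDFs or as plain-text
exports of them. Both are reduced to the same in-memory form,
:class:`DocumentText`: ordered pages of ordered lines, each line
addressable by ``(page_number, line_number)`` so downstream records can
point back at their source. Character-level normalization (Unicode
spaces and minus signs, trailing whitespace) is a separate explicit
step because PDF text extractors routinely emit typographic variants
that would defeat ASCII-based coordinate grammars.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, replace
from pathlib import Path

from ._pdf import (EncryptedPdfError, PdfError, UnsupportedPdfError,
                   extract_pages)

__all__ = [
    "Page",
    "DocumentText",
    "DocumentError",
    "EncryptedPdfError",
    "UnsupportedPdfError",
    "PdfError",
    "read_document",
    "normalize_lines",
    "document_from_lines",
]


class DocumentError(Exception):
    """Problem reading an input document."""


@dataclass(frozen=True)
class Page:
    """One page: 1-based number and its lines in reading order."""

    number: int
    lines: tuple[str, ...]


@dataclass(frozen=True)
class DocumentText:
    """Ordered pages of ordered text lines with provenance addressing."""

    source_kind: str  # "pdf" or "text"
    pages: tuple[Page, ...]

    def line(self, page_number: int, line_number: int) -> str:
        """The line at 1-based ``(page_number, line_number)``."""
        return self.pages[page_number - 1].lines[line_number - 1]

    def iter_lines(self):
        """Yield ``(page_number, line_number, text)`` in document order."""
        for page in self.pages:
            for i, text in enumerate(page.lines, start=1):
                yield page.number, i, text

    @property
    def n_lines(self) -> int:
        return sum(len(p.lines) for p in self.pages)


def document_from_lines(pages: list[list[str]],
                        source_kind: str = "text") -> DocumentText:
    """Build a DocumentText from already-split pages of lines."""
    return DocumentText(
        source_kind=source_kind,
        pages=tuple(Page(number=i, lines=tuple(lines))
                    for i, lines in enumerate(pages, start=1)),
    )


def _split_text(content: str) -> list[list[str]]:
    """Split file content into pages (form feeds) of lines."""
    content = content.replace("\r\n", "\n").replace("\r", "\n")
    pages = []
    for segment in content.split("\f"):
        if segment.endswith("\n"):
            segment = segment[:-1]
        pages.append(segment.split("\n") if segment else [])
    # an empty file is one page with zero lines, not zero pages
    return pages or [[]]


def read_document(path: str | Path, kind: str = "auto") -> DocumentText:
    """Read a PDF or plain-text file into a :class:`DocumentText`.

    ``kind='auto'`` resolves by extension (``.pdf`` -> pdf, else text).
    Plain text becomes a single page unless form feeds delimit pages.
    Encrypted or structurally unsupported PDFs raise
    :class:`EncryptedPdfError` / :class:`UnsupportedPdfError`, whose
    messages point at the save-as-text fallback.
    """
    path = Path(path)
    if kind == "auto":
        kind = "pdf" if path.suffix.lower() == ".pdf" else "text"
    if kind not in ("pdf", "text"):
        raise ValueError(f"unknown document kind: {kind!r}")

    if kind == "pdf":
        data = path.read_bytes()
        pages = extract_pages(data)
        return document_from_lines(pages, source_kind="pdf")

    raw = path.read_bytes()
    try:
        content = raw.decode("utf-8")
    except UnicodeDecodeError:
        content = raw.decode("latin-1")
    return document_from_lines(_split_text(content), source_kind="text")


# Unicode space variants mapped to ASCII space; tab is deliberately kept.
_SPACE_CHARS = "".join(
    chr(c) for c in range(0x10000)
    if unicodedata.category(chr(c)) == "Zs" and chr(c) != " "
)
_DASH_CHARS = "−‐‑‒–—―"
_NORMALIZE = str.maketrans(
    dict.fromkeys(_SPACE_CHARS, " ") | dict.fromkeys(_DASH_CHARS, "-")
)


def _normalize_line(text: str) -> str:
    return text.translate(_NORMALIZE).rstrip(" \t")


def normalize_lines(doc: DocumentText) -> DocumentText:
    """Normalize characters line by line; structure is unchanged.

    Unicode space variants become ASCII spaces, Unicode minus/dash
    variants become ``-``, trailing whitespace is stripped. Tabs are
    preserved (they carry delimiter information). Idempotent.
    """
    pages = tuple(
        replace(page, lines=tuple(_normalize_line(t) for t in page.lines))
        for page in doc.pages
    )
    return replace(doc, pages=pages)
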