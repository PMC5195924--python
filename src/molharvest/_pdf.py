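"""Minimal PDF text support for single-column supplementary documents.

This module implements just enough of the PDF object model to (a) render
the plain-text fixtures produced by :mod:`molharvest.fixtures` as
well-formed single-column PDFs and (b) extract text lines, in reading
order, from such PDFs and from similarly simple real-world documents
(uncompressed or Flate-compressed content streams, standard one-byte
string encodings, single-column layout).

It is deliberately not a general PDF library: encrypted files, object
streams / cross-reference streams (PDF 1.5 compression), CID/CMap
encoded fonts and multi-column layouts are out of scope and raise
errors that point the caller at the plain-text export fallback.
"""

from __future__ import annotations

import re
import zlib

__all__ = [
    "PdfError",
    "EncryptedPdfError",
    "UnsupportedPdfError",
    "render_pdf",
    "extract_pages",
]


class PdfError(Exception):
    """Base error for PDF reading problems."""


class EncryptedPdfError(PdfError):
    """The PDF is encrypted; save it as plain text and use the text path."""


class UnsupportedPdfError(PdfError):
    """The PDF uses features outside this reader's scope."""


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------

_ESCAPES = {ord("\\"): b"\\\\", ord("("): b"\\(", ord(")"): b"\\)",
            ord("\t"): b"\\t", ord("\r"): b"\\r", ord("\n"): b"\\n"}


def _pdf_string(text: str) -> bytes:
    out = bytearray(b"(")
    for ch in text.encode("latin-1", errors="replace"):
        esc = _ESCAPES.get(ch)
        if esc is not None:
            out += esc
        elif ch < 32:
            out += b"\\%03o" % ch
        else:
            out.append(ch)
    out += b")"
    return bytes(out)


def render_pdf(pages: list[list[str]], *, font_size: float = 10.0,
               leading: float = 12.0, margin: float = 50.0,
               page_width: float = 612.0, page_height: float = 792.0) -> bytes:
    """Render pages of text lines as a single-column Helvetica PDF.

    Each inner list is one page, lines in top-to-bottom reading order.
    Output is deterministic for identical input.
    """
    n = max(len(pages), 1)
    page_lists = pages if pages else [[]]

    objects: dict[int, bytes] = {}
    font_obj = 3
    first_page_obj = 4
    kids = " ".join(f"{first_page_obj + 2 * i} 0 R" for i in range(n))
    objects[1] = b"<< /Type /Catalog /Pages 2 0 R >>"
    objects[2] = (f"<< /Type /Pages /Kids [{kids}] /Count {n} >>").encode()
    objects[font_obj] = (b"<< /Type /Font /Subtype /Type1 "
                         b"/BaseFont /Helvetica >>")

    for i, lines in enumerate(page_lists):
        page_obj = first_page_obj + 2 * i
        content_obj = page_obj + 1
        objects[page_obj] = (
            f"<< /Type /Page /Parent 2 0 R "
            f"/MediaBox [0 0 {page_width:g} {page_height:g}] "
            f"/Resources << /Font << /F1 {font_obj} 0 R >> >> "
            f"/Contents {content_obj} 0 R >>"
        ).encode()
        parts = [b"BT", b"/F1 %g Tf" % font_size,
                 b"%g %g Td" % (margin, page_height - margin - font_size)]
        for j, line in enumerate(lines):
            if j > 0:
                parts.append(b"0 %g Td" % -leading)
            parts.append(_pdf_string(line) + b" Tj")
        parts.append(b"ET")
        stream = b"\n".join(parts)
        objects[content_obj] = (
            b"<< /Length %d >>\nstream\n" % len(stream)
            + stream + b"\nendstream"
        )

    buf = bytearray(b"%PDF-1.4\n%\xe2\xe3\xcf\xd3\n")
    offsets: dict[int, int] = {}
    for num in sorted(objects):
        offsets[num] = len(buf)
        buf += b"%d 0 obj\n" % num + objects[num] + b"\nendobj\n"
    xref_at = len(buf)
    nobj = max(objects) + 1
    buf += b"xref\n0 %d\n" % nobj
    buf += b"0000000000 65535 f \n"
    for num in range(1, nobj):
        buf += b"%010d 00000 n \n" % offsets[num]
    buf += (b"trailer\n<< /Size %d /Root 1 0 R >>\nstartxref\n%d\n%%%%EOF\n"
            % (nobj, xref_at))
    return bytes(buf)


# ---------------------------------------------------------------------------
# Reader: object scanning
# ---------------------------------------------------------------------------

_OBJ_HEAD = re.compile(rb"(\d+)\s+\d+\s+obj\b")
_LENGTH = re.compile(rb"/Length\s+(\d+)(?!\s+\d+\s+R)")
_REF = re.compile(rb"(\d+)\s+\d+\s+R")


def _scan_objects(data: bytes) -> dict[int, tuple[bytes, bytes | None]]:
    """Map object number -> (dict/body bytes, stream bytes or None)."""
    objects: dict[int, tuple[bytes, bytes | None]] = {}
    pos = 0
    while True:
        m = _OBJ_HEAD.search(data, pos)
        if m is None:
            break
        num = int(m.group(1))
        body_start = m.end()
        stream_at = data.find(b"stream", body_start)
        endobj_at = data.find(b"endobj", body_start)
        if endobj_at == -1:
            endobj_at = len(data)
        if stream_at != -1 and stream_at < endobj_at:
            head = data[body_start:stream_at]
            data_start = stream_at + len(b"stream")
            if data[data_start:data_start + 2] == b"\r\n":
                data_start += 2
            elif data[data_start:data_start + 1] in (b"\n", b"\r"):
                data_start += 1
            lm = _LENGTH.search(head)
            if lm is not None:
                data_end = data_start + int(lm.group(1))
            else:  # indirect /Length: fall back to the endstream keyword
                data_end = data.find(b"endstream", data_start)
                if data_end == -1:
                    raise UnsupportedPdfError("unterminated stream object")
            stream = data[data_start:data_end]
            endobj_at = data.find(b"endobj", data_end)
            if endobj_at == -1:
                endobj_at = len(data)
            objects[num] = (head, stream)
        else:
            objects[num] = (data[body_start:endobj_at], None)
        pos = endobj_at + len(b"endobj")
    return objects


def _page_order(data: bytes,
                objects: dict[int, tuple[bytes, bytes | None]]) -> list[int]:
    """Object numbers of the pages, in document order."""
    root = None
    for m in re.finditer(rb"/Root\s+(\d+)\s+\d+\s+R", data):
        root = int(m.group(1))
    pages_ref = None
    if root is not None and root in objects:
        pm = re.search(rb"/Pages\s+(\d+)\s+\d+\s+R", objects[root][0])
        if pm is not None:
            pages_ref = int(pm.group(1))

    def walk(num: int, out: list[int]) -> None:
        body = objects[num][0]
        if re.search(rb"/Type\s*/Pages\b", body):
            km = re.search(rb"/Kids\s*\[([^\]]*)\]", body)
            if km is not None:
                for rm in _REF.finditer(km.group(1)):
                    child = int(rm.group(1))
                    if child in objects:
                        walk(child, out)
        elif re.search(rb"/Type\s*/Page\b", body):
            out.append(num)

    order: list[int] = []
    if pages_ref is not None and pages_ref in objects:
        walk(pages_ref, order)
    if not order:  # damaged tree: fall back to numeric object order
        for num in sorted(objects):
            body, _ = objects[num]
            if re.search(rb"/Type\s*/Page\b", body) and not re.search(
                    rb"/Type\s*/Pages\b", body):
                order.append(num)
    return order


def _decode_stream(head: bytes, stream: bytes) -> bytes:
    if re.search(rb"/Filter\s*/FlateDecode\b", head) or re.search(
            rb"/Filter\s*\[\s*/FlateDecode\s*\]", head):
        try:
            return zlib.decompress(stream)
        except zlib.error as exc:
            raise UnsupportedPdfError(f"bad Flate stream: {exc}") from exc
    if re.search(rb"/Filter", head):
        raise UnsupportedPdfError("unsupported stream filter")
    return stream


# ---------------------------------------------------------------------------
# Reader: content-stream interpretation
# ---------------------------------------------------------------------------

_STRING_ESCAPES = {b"n": "\n", b"r": "\r", b"t": "\t", b"b": "\b",
                   b"f": "\f", b"(": "(", b")": ")", b"\\": "\\"}


def _tokenize(content: bytes):
    """Yield ('str', text) | ('num', float) | ('op', name) | ('name', name)."""
    i, n = 0, len(content)
    while i < n:
        c = content[i:i + 1]
        if c in b" \t\r\n\x00\f":
            i += 1
        elif c == b"%":
            j = content.find(b"\n", i)
            i = n if j == -1 else j + 1
        elif c == b"(":
            depth, i = 1, i + 1
            out: list[str] = []
            while i < n and depth:
                ch = content[i:i + 1]
                if ch == b"\\":
                    nxt = content[i + 1:i + 2]
                    if nxt in _STRING_ESCAPES:
                        out.append(_STRING_ESCAPES[nxt])
                        i += 2
                    elif nxt.isdigit():
                        j = i + 1
                        while j < min(i + 4, n) and content[j:j + 1].isdigit():
                            j += 1
                        out.append(chr(int(content[i + 1:j], 8) & 0xFF))
                        i = j
                    elif nxt in b"\r\n":  # line continuation
                        i += 2
                        if nxt == b"\r" and content[i:i + 1] == b"\n":
                            i += 1
                    else:
                        i += 1
                else:
                    if ch == b"(":
                        depth += 1
                    elif ch == b")":
                        depth -= 1
                        if depth == 0:
                            i += 1
                            break
                    out.append(ch.decode("latin-1"))
                    i += 1
            yield ("str", "".join(out))
        elif c == b"<":
            if content[i + 1:i + 2] == b"<":
                i += 2
                yield ("op", "<<")
            else:
                j = content.find(b">", i)
                j = n if j == -1 else j
                hexdigits = re.sub(rb"\s", b"", content[i + 1:j])
                if len(hexdigits) % 2:
                    hexdigits += b"0"
                yield ("str", bytes.fromhex(hexdigits.decode("ascii",
                                                             "ignore"))
                       .decode("latin-1"))
                i = j + 1
        elif c == b">" and content[i + 1:i + 2] == b">":
            i += 2
            yield ("op", ">>")
        elif c in b"[]":
            i += 1
            yield ("op", c.decode())
        elif c == b"/":
            m = re.match(rb"/[^\s()<>\[\]{}/%]*", content[i:])
            yield ("name", m.group(0).decode("latin-1"))
            i += len(m.group(0))
        else:
            m = re.match(rb"[-+.0-9]+", content[i:])
            if m and re.fullmatch(rb"[-+]?(\d+\.?\d*|\.\d+)", m.group(0)):
                yield ("num", float(m.group(0)))
                i += len(m.group(0))
            else:
                m = re.match(rb"[^\s()<>\[\]{}/%]+", content[i:])
                if m is None:
                    i += 1
                    continue
                yield ("op", m.group(0).decode("latin-1"))
                i += len(m.group(0))


def _extract_text_runs(content: bytes) -> list[tuple[float, float, str]]:
    """(y, x, text) for every shown string, in text-space coordinates."""
    runs: list[tuple[float, float, str]] = []
    x = y = 0.0
    leading = 0.0
    array_marker = object()
    stack: list[object] = []

    def show(text: str) -> None:
        if text:
            runs.append((y, x, text))

    for kind, value in _tokenize(content):
        if kind in ("num", "str", "name"):
            stack.append(value)
            continue
        op = value
        if op == "[":
            stack.append(array_marker)
            continue
        if op == "]":
            continue  # keep array contents on the stack for TJ
        if op == "BT":
            x = y = 0.0
        elif op in ("Td", "TD") and len(stack) >= 2:
            ty = stack[-1]
            tx = stack[-2]
            if isinstance(tx, float) and isinstance(ty, float):
                x += tx
                y += ty
                if op == "TD":
                    leading = -ty
        elif op == "Tm" and len(stack) >= 6:
            e, f = stack[-2], stack[-1]
            if isinstance(e, float) and isinstance(f, float):
                x, y = e, f
        elif op == "TL" and stack and isinstance(stack[-1], float):
            leading = stack[-1]
        elif op == "T*":
            y -= leading
        elif op == "Tj" and stack and isinstance(stack[-1], str):
            show(stack[-1])
        elif op == "'" and stack and isinstance(stack[-1], str):
            y -= leading
            show(stack[-1])
        elif op == '"' and stack and isinstance(stack[-1], str):
            y -= leading
            show(stack[-1])
        elif op == "TJ":
            # array elements sit on the stack above the marker; keep strings
            j = len(stack) - 1
            parts: list[str] = []
            while j >= 0 and stack[j] is not array_marker:
                if isinstance(stack[j], str):
                    parts.append(stack[j])
                j -= 1
            show("".join(reversed(parts)))
        if op not in ("<<", ">>"):
            stack.clear()
    return runs


def _runs_to_lines(runs: list[tuple[float, float, str]],
                   y_tolerance: float = 2.0) -> list[str]:
    if not runs:
        return []
    runs = sorted(runs, key=lambda r: (-r[0], r[1]))
    lines: list[str] = []
    current: list[tuple[float, str]] = []
    current_y = runs[0][0]
    for ry, rx, text in runs:
        if abs(ry - current_y) > y_tolerance:
            current.sort(key=lambda t: t[0])
            lines.append("".join(t for _, t in current))
            current = []
            current_y = ry
        current.append((rx, text))
    current.sort(key=lambda t: t[0])
    lines.append("".join(t for _, t in current))
    return lines


def extract_pages(data: bytes) -> list[list[str]]:
    """Extract text lines per page, top-to-bottom, from a simple PDF."""
    if not data.startswith(b"%PDF"):
        raise PdfError("not a PDF file (missing %PDF header)")
    if re.search(rb"/Encrypt\s+\d+\s+\d+\s+R", data):
        raise EncryptedPdfError(
            "encrypted PDF; save the document as plain text and re-run "
            "with kind='text'")
    objects = _scan_objects(data)
    if not objects:
        raise UnsupportedPdfError(
            "no readable objects (cross-reference/object streams are not "
            "supported); save the document as plain text and re-run with "
            "kind='text'")
    page_objs = _page_order(data, objects)
    if not page_objs:
        raise UnsupportedPdfError(
            "no page objects found; save the document as plain text and "
            "re-run with kind='text'")
    pages: list[list[str]] = []
    for num in page_objs:
        body, _ = objects[num]
        content_refs: list[int] = []
        cm = re.search(rb"/Contents\s+(\d+)\s+\d+\s+R", body)
        if cm is not None:
            content_refs.append(int(cm.group(1)))
        else:
            am = re.search(rb"/Contents\s*\[([^\]]*)\]", body)
            if am is not None:
                content_refs.extend(int(r.group(1))
                                    for r in _REF.finditer(am.group(1)))
        chunks: list[bytes] = []
        for ref in content_refs:
            if ref in objects and objects[ref][1] is not None:
                head, stream = objects[ref]
                chunks.append(_decode_stream(head, stream))
        runs = _extract_text_runs(b"\n".join(chunks))
        pages.append(_runs_to_lines(runs))
    return pages
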