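"""Group coordinate lines into molecule blocks and aggregate reports.

A molecule in a supplementary document is a maximal run of coordinate
lines. Page furniture -- blank lines, page numbers ("14", "S14",
"Page 3"), running headers repeated across pages -- may interrupt a run
mid-molecule; such interruptions are healed so a paginated molecule is
recovered as one block, while any substantive text (prose, energies,
the next molecule's title) terminates the run. Runs whose first column
is a serial index 1, 2, 3, ... are numeric-table noise, not atoms, and
are dropped.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .ingest import DocumentText
from .patterns import AtomRecord, parse_coordinate_line

__all__ = [
    "MoleculeBlock",
    "ExtractionReport",
    "segment_blocks",
    "attach_labels",
    "build_report",
]

#: Page-number-like lines: a bare integer, optionally preceded by a short
#: alphabetic tag ("S14", "Page 3", "A-7"). Supplementary documents number
#: pages in all of these styles.
_PAGE_TAG = re.compile(r"^(?:[A-Za-z]{1,4}[-. ]?)?[0-9]{1,4}$")

#: A running header/footer must recur on at least this many distinct pages.
_HEADER_MIN_PAGES = 3

#: A run survives at most this many buffered ignorable lines in a row.
_MAX_GAP = 5


@dataclass
class MoleculeBlock:
    """One candidate molecule: ordered atoms plus provenance and flags."""

    block_id: int
    atoms: list[AtomRecord]
    label: str | None = None
    span: tuple[tuple[int, int], tuple[int, int]] | None = None
    flags: set[str] = field(default_factory=set)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]


@dataclass
class ExtractionReport:
    """Counts and warnings for one extraction run."""

    delimiter: str
    total_lines: int
    coordinate_lines: int
    n_blocks: int
    n_atoms: int
    per_block_atom_counts: list[int]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "delimiter": self.delimiter,
            "total_lines": self.total_lines,
            "coordinate_lines": self.coordinate_lines,
            "blocks": self.n_blocks,
            "atoms": self.n_atoms,
            "per_block_atom_counts": self.per_block_atom_counts,
            "warnings": self.warnings,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        lines = [
            f"delimiter: {self.delimiter}",
            f"total lines: {self.total_lines}",
            f"coordinate lines: {self.coordinate_lines}",
            f"blocks: {self.n_blocks}",
            f"atoms: {self.n_atoms}",
            "atoms per block: "
            + " ".join(str(c) for c in self.per_block_atom_counts),
        ]
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines) + "\n"


def _recurring_texts(doc: DocumentText) -> set[str]:
    """Non-empty line texts that appear on >= 3 distinct pages."""
    pages_seen: dict[str, set[int]] = {}
    for p, _, text in doc.iter_lines():
        key = text.strip()
        if key:
            pages_seen.setdefault(key, set()).add(p)
    return {t for t, pages in pages_seen.items()
            if len(pages) >= _HEADER_MIN_PAGES}


def _is_ignorable(text: str, recurring: set[str]) -> bool:
    stripped = text.strip()
    return (stripped == "" or _PAGE_TAG.fullmatch(stripped) is not None
            or stripped in recurring)


def _is_serial_run(atoms: list[AtomRecord]) -> bool:
    tokens = [a.raw_first_token for a in atoms]
    if not all(t.isdigit() for t in tokens):
        return False
    return [int(t) for t in tokens] == list(range(1, len(tokens) + 1))


def _segment(doc: DocumentText, delim: str, min_atoms: int,
             allow_scientific: bool):
    """Core pass: (kept blocks, dropped runs as (reason, atoms) pairs)."""
    if min_atoms < 1:
        raise ValueError("min_atoms must be >= 1")
    recurring = _recurring_texts(doc)
    kept: list[MoleculeBlock] = []
    dropped: list[tuple[str, list[AtomRecord]]] = []
    current: list[AtomRecord] = []
    healed = False
    gap = 0

    def close() -> None:
        nonlocal current, healed, gap
        if current:
            if _is_serial_run(current):
                dropped.append(("suspicious_serial_elements", current))
            elif len(current) < min_atoms:
                dropped.append(("below_min_atoms", current))
            else:
                flags = set()
                if healed or current[0].source[0] != current[-1].source[0]:
                    flags.add("spans_pages")
                kept.append(MoleculeBlock(
                    block_id=len(kept) + 1,
                    atoms=current,
                    span=(current[0].source, current[-1].source),
                    flags=flags,
                ))
        current, healed, gap = [], False, 0

    for p, ln, text in doc.iter_lines():
        record = parse_coordinate_line(text, delim, source=(p, ln),
                                       allow_scientific=allow_scientific)
        if record is not None:
            if current and gap:
                healed = True
            gap = 0
            current.append(record)
        elif current:
            if _is_ignorable(text, recurring) and gap < _MAX_GAP:
                gap += 1
            else:
                close()
    close()
    return kept, dropped


def segment_blocks(doc: DocumentText, delim: str, min_atoms: int = 2, *,
                   allow_scientific: bool = False) -> list[MoleculeBlock]:
    """Split a document into molecule blocks.

    A block is a maximal run of coordinate lines; runs survive up to
    five consecutive ignorable interruptions (blank lines, page
    numbers, recurring headers) -- the pagination-healing rule -- and
    are terminated by any other non-coordinate line. Runs smaller than
    ``min_atoms`` and serial-index table runs are dropped (they are
    reported by :func:`build_report`).
    """
    kept, _ = _segment(doc, delim, min_atoms, allow_scientific)
    return kept


def attach_labels(blocks: list[MoleculeBlock], doc: DocumentText,
                  delim: str, *, lookback: int = 3,
                  max_len: int = 80) -> list[MoleculeBlock]:
    """Attach to each block the nearest preceding title-like line.

    The label is the nearest non-empty, non-coordinate, non-ignorable
    line within ``lookback`` lines above the block start, truncated to
    ``max_len`` characters. Atoms are never modified.
    """
    flat = list(doc.iter_lines())
    index_of = {(p, ln): i for i, (p, ln, _) in enumerate(flat)}
    recurring = _recurring_texts(doc)
    for block in blocks:
        block.label = None
        start = index_of.get(block.span[0]) if block.span else None
        if start is None:
            continue
        for i in range(start - 1, max(start - 1 - lookback, -1), -1):
            text = flat[i][2]
            if _is_ignorable(text, recurring):
                continue
            if parse_coordinate_line(text, delim) is not None:
                continue
            block.label = text.strip()[:max_len]
            break
    return blocks


def build_report(doc: DocumentText, delim: str,
                 blocks: list[MoleculeBlock], *, min_atoms: int = 2,
                 allow_scientific: bool = False) -> ExtractionReport:
    """Aggregate counts and dropped-run warnings for a document."""
    _, dropped = _segment(doc, delim, min_atoms, allow_scientific)
    n_coord = sum(b.n_atoms for b in blocks) + sum(
        len(atoms) for _, atoms in dropped)
    warnings = []
    for reason, atoms in dropped:
        at = atoms[0].source
        if reason == "suspicious_serial_elements":
            warnings.append(
                f"dropped serial-index run of {len(atoms)} lines starting "
                f"at page {at[0]} line {at[1]}")
        else:
            warnings.append(
                f"dropped block of {len(atoms)} atom(s) below min_atoms "
                f"at page {at[0]} line {at[1]}")
    return ExtractionReport(
        delimiter=delim,
        total_lines=doc.n_lines,
        coordinate_lines=n_coord,
        n_blocks=len(blocks),
        n_atoms=sum(b.n_atoms for b in blocks),
        per_block_atom_counts=[b.n_atoms for b in blocks],
        warnings=warnings,
    )
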