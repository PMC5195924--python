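"""Line classification and parsing of atomic-coordinate records.

Two parsers coexist on purpose. The *reference patterns* are the two
legacy regular expressions historically used to harvest space- and
comma-delimited coordinate tables; they are shipped byte-for-byte
(host-language double backslashes collapsed to single ones) and
evaluated with standard anchored-match semantics, permissive wildcards
and all, as a fidelity baseline. The *canonical parser* implements a strict grammar
-- element symbol or atomic number, then at least three fixed-decimal
fields in a declared delimiter dialect -- and is what the pipeline
actually uses. On well-formed coordinate lines the canonical parser is
deliberately no more permissive than the reference pattern of the same
dialect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "ELEMENTS",
    "SYMBOL_TO_Z",
    "PAPER_PATTERN_SPACE",
    "PAPER_PATTERN_COMMA",
    "DELIMITERS",
    "AtomRecord",
    "match_paper_pattern",
    "normalize_element",
    "atomic_number",
    "parse_coordinate_line",
    "detect_delimiter",
]

# ---------------------------------------------------------------------------
# Periodic table (symbols for Z = 1..118)
# ---------------------------------------------------------------------------

ELEMENTS: tuple[str, ...] = (
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm",
    "Md", "No", "Lr", "Rf", "Db", "Sg", "Bh", "Hs", "Mt", "Ds",
    "Rg", "Cn", "Nh", "Fl", "Mc", "Lv", "Ts", "Og",
)

SYMBOL_TO_Z: dict[str, int] = {s: z for z, s in enumerate(ELEMENTS, start=1)}


def atomic_number(symbol: str) -> int:
    """Atomic number of a canonical element symbol."""
    return SYMBOL_TO_Z[symbol]


# ---------------------------------------------------------------------------
# Reference patterns (verbatim; anchored full-line match)
# ---------------------------------------------------------------------------

#: Space-delimited reference expression, kept verbatim. The ``.{1,2}``
#: wildcards and ``.{1,}`` tail are part of the legacy expression and
#: are not repaired here.
PAPER_PATTERN_SPACE = (
    r"^[A-Za-z0-9]{1,2}\s+-{0,1}.{1,2}[0-9]{1,8}"
    r"\s+-{0,1}.{1,2}[0-9]{1,8}.{1,}"
)

#: Comma-delimited reference expression, kept verbatim.
PAPER_PATTERN_COMMA = (
    r"^[A-Za-z0-9]{1,2}\,[0]{0,1}[\,]{0,1}-{0,1}.{1,2}[0-9]{1,10}"
    r"\,-{0,1}.{1,2}[0-9]{1,10}.{1,}"
)

_PAPER_PATTERNS = {
    "space": re.compile(PAPER_PATTERN_SPACE),
    "comma": re.compile(PAPER_PATTERN_COMMA),
    "space_dialect": re.compile(PAPER_PATTERN_SPACE),
    "comma_dialect": re.compile(PAPER_PATTERN_COMMA),
}


def match_paper_pattern(line: str, pattern_id: str) -> bool:
    """Anchored (whole-line) match of a verbatim reference pattern.

    ``pattern_id`` is ``"space"``/``"space_dialect"`` or
    ``"comma"``/``"comma_dialect"``. Matching follows plain
    regular-expression semantics; the permissive constructs in the
    printed expressions are applied exactly as written.
    """
    try:
        pattern = _PAPER_PATTERNS[pattern_id]
    except KeyError:
        raise ValueError(f"unknown pattern_id: {pattern_id!r}") from None
    return pattern.fullmatch(line) is not None


# ---------------------------------------------------------------------------
# Canonical parsing
# ---------------------------------------------------------------------------

DELIMITERS = ("space", "comma", "tab")

#: Fixed-decimal coordinate field: optional sign, digits, optional
#: decimal point with 1-10 fractional digits. Scientific notation is
#: rejected unless explicitly enabled.
_NUMBER = re.compile(r"[+-]?[0-9]+(?:\.[0-9]{1,10})?")
_NUMBER_SCI = re.compile(
    r"[+-]?[0-9]+(?:\.[0-9]{1,10})?(?:[eEdD][+-]?[0-9]{1,3})?")

_MAX_COORD = 1.0e6


@dataclass(frozen=True)
class AtomRecord:
    """One parsed atom: canonical element, Cartesian position in Angstrom.

    ``raw_first_token`` keeps the original first column (``"16"`` vs
    ``"S"``) for block-level plausibility checks; ``source`` is the
    ``(page_number, line_number)`` provenance of the line.
    """

    element: str
    x: float
    y: float
    z: float
    raw_first_token: str
    source: tuple[int, int] | None = None

    @property
    def position(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


def normalize_element(token: str) -> str | None:
    """Canonical element symbol for a first-column token, or None.

    All-digit tokens are atomic numbers (1..118); alphabetic tokens are
    case-normalized symbols; anything mixed or unknown is rejected.
    """
    if not token or len(token) > 3:
        return None
    if token.isdigit():
        z = int(token)
        return ELEMENTS[z - 1] if 1 <= z <= 118 else None
    if token.isalpha():
        canonical = token[0].upper() + token[1:].lower()
        return canonical if canonical in SYMBOL_TO_Z else None
    return None


def _tokenize(line: str, delim: str) -> list[str] | None:
    if delim == "space":
        # strictly space-separated; a leading space means no valid first
        # column (coordinate rows start flush left in these documents)
        if line.startswith(" "):
            return None
        return [t for t in line.split(" ") if t != ""] if line else []
    if delim == "comma":
        return [t.strip(" \t") for t in line.split(",")]
    if delim == "tab":
        return [t.strip(" ") for t in line.split("\t")]
    raise ValueError(f"delimiter must be one of {DELIMITERS}, got {delim!r}")


def parse_coordinate_line(line: str, delim: str, *,
                          source: tuple[int, int] | None = None,
                          allow_scientific: bool = False
                          ) -> AtomRecord | None:
    """Parse one line as an atomic-coordinate record; None if it is not.

    A record is: an element token (symbol or atomic number), then at
    least three numeric fields in fixed-decimal form, separated by the
    concrete delimiter. Extra trailing fields are tolerated only if
    they are numeric too; the first three numbers are x, y, z. This
    operation is total: malformed lines yield None, never an error.
    """
    tokens = _tokenize(line, delim)
    if tokens is None or len(tokens) < 4:
        return None
    element = normalize_element(tokens[0])
    if element is None:
        return None
    number = _NUMBER_SCI if allow_scientific else _NUMBER
    values: list[float] = []
    for tok in tokens[1:]:
        if number.fullmatch(tok) is None:
            return None
        values.append(float(tok.replace("D", "E").replace("d", "e"))
                      if allow_scientific else float(tok))
    if len(values) < 3:
        return None
    x, y, z = values[:3]
    if any(abs(v) >= _MAX_COORD for v in (x, y, z)):
        return None
    return AtomRecord(element=element, x=x, y=y, z=z,
                      raw_first_token=tokens[0], source=source)


def detect_delimiter(doc, *, allow_scientific: bool = False) -> str:
    """Pick the concrete delimiter that parses the most lines.

    Ties (including the all-zero case) resolve by the fixed priority
    space > comma > tab.
    """
    counts = dict.fromkeys(DELIMITERS, 0)
    for _, _, text in doc.iter_lines():
        for delim in DELIMITERS:
            if parse_coordinate_line(text, delim,
                                     allow_scientific=allow_scientific):
                counts[delim] += 1
    best = max(DELIMITERS, key=lambda d: counts[d])  # ties: listed order
    return best
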