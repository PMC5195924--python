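"""Synthetic supplementary-information documents with ground truth.

Real supplementary PDFs mix per-molecule coordinate tables with titles,
prose about methods, energy statements, page numbers and running
headers, in space-, comma- or tab-delimited dialects, with anywhere
from two to eight printed decimals, and with page breaks that can fall
in the middle of a molecule's table. This module emulates exactly that
mix and records everything it emitted in a :class:`FixtureManifest`,
so every pipeline stage can be tested against known truth without
downloading copyrighted supplements.

Coordinates are kept within |v| <= 9.4 A. Small-molecule geometries in
published supplements are centred near the origin and rarely exceed a
single integer digit, and the reference regular expressions shipped in
:mod:`molharvest.patterns` only cover that width; the fixtures emulate
the documents those expressions were written for.

Toy geometries are idealized (standard bond lengths and angles), not
DFT-optimized; each library entry carries its expected bond count
under default perception.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, asdict

import numpy as np

from . import _pdf
from .patterns import SYMBOL_TO_Z

__all__ = [
    "ToyMolecule",
    "toy_molecule_library",
    "FixtureSpec",
    "FixtureManifest",
    "generate_document",
    "render_fixture_pdf",
    "adversarial_noise_bank",
]


# ---------------------------------------------------------------------------
# Toy molecule library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyMolecule:
    """Idealized geometry plus its expected default-perception bond count."""

    name: str
    elements: tuple[str, ...]
    coords: tuple[tuple[float, float, float], ...]
    expected_bonds: int


def _methane() -> ToyMolecule:
    d = 1.09 / math.sqrt(3.0)
    corners = [(d, d, d), (d, -d, -d), (-d, d, -d), (-d, -d, d)]
    return ToyMolecule("methane", ("C", "H", "H", "H", "H"),
                       ((0.0, 0.0, 0.0), *corners), expected_bonds=4)


def _ethane() -> ToyMolecule:
    # staggered, C-C 1.54 A along z, C-H 1.09 A at the tetrahedral angle
    cc, ch = 1.54, 1.09
    theta = math.radians(180.0 - 109.47)
    rho, dz = ch * math.sin(theta), ch * math.cos(theta)
    elements = ["C", "C"]
    coords = [(0.0, 0.0, 0.0), (0.0, 0.0, cc)]
    for base_z, z_sign, phase in ((0.0, -1.0, 0.0), (cc, 1.0, 60.0)):
        for k in range(3):
            phi = math.radians(phase + 120.0 * k)
            elements.append("H")
            coords.append((rho * math.cos(phi), rho * math.sin(phi),
                           base_z + z_sign * dz))
    return ToyMolecule("ethane", tuple(elements),
                       tuple(coords), expected_bonds=7)


def _benzene() -> ToyMolecule:
    rc, rh = 1.39, 1.39 + 1.09
    elements, coords = [], []
    for r, el in ((rc, "C"), (rh, "H")):
        for k in range(6):
            phi = math.radians(60.0 * k)
            elements.append(el)
            coords.append((r * math.cos(phi), r * math.sin(phi), 0.0))
    return ToyMolecule("benzene", tuple(elements), tuple(coords),
                       expected_bonds=12)


def _dimethyl_sulfide() -> ToyMolecule:
    # C-S-C 99 deg, S-C 1.81 A, methyl hydrogens at 1.09 A
    sc, ch = 1.81, 1.09
    half = math.radians(99.0 / 2.0)
    c1 = np.array([sc * math.sin(half), sc * math.cos(half), 0.0])
    c2 = np.array([-sc * math.sin(half), sc * math.cos(half), 0.0])
    elements = ["S", "C", "C"]
    coords = [np.zeros(3), c1, c2]
    theta = math.radians(109.47)
    for c in (c1, c2):
        axis = c / np.linalg.norm(c)  # methyl axis away from S
        # orthonormal frame around the axis
        ref = np.array([0.0, 0.0, 1.0])
        u = np.cross(axis, ref)
        u /= np.linalg.norm(u)
        v = np.cross(axis, u)
        for k in range(3):
            phi = math.radians(120.0 * k)
            direction = (math.cos(theta) * (-axis)
                         + math.sin(theta) * (math.cos(phi) * u
                                              + math.sin(phi) * v))
            # H points away from S: reflect about the methyl axis
            direction = -direction
            elements.append("H")
            coords.append(c + ch * direction)
    return ToyMolecule("dimethyl sulfide", tuple(elements),
                       tuple(tuple(float(x) for x in p) for p in coords),
                       expected_bonds=8)


def _water() -> ToyMolecule:
    return ToyMolecule("water", ("O", "H", "H"),
                       ((0.0, 0.0, 0.0), (0.9572, 0.0, 0.0),
                        (-0.2399, 0.9266, 0.0)), expected_bonds=2)


def toy_molecule_library() -> dict[str, ToyMolecule]:
    """Named idealized geometries used to build fixtures."""
    mols = [_water(), _methane(), _ethane(), _benzene(),
            _dimethyl_sulfide()]
    return {m.name: m for m in mols}


# ---------------------------------------------------------------------------
# Noise vocabulary
# ---------------------------------------------------------------------------

_PROSE = (
    "Optimized geometries and calculated single point energies.",
    "All stationary points were characterized by frequency analysis.",
    "Cartesian coordinates of the optimized structures are listed below.",
    "Relative energies are given in kcal/mol at 298 K.",
    "The potential energy surface was scanned along the reaction "
    "coordinate.",
    "Imaginary frequency: 1 (transition state).",
)

_ENERGY_TEMPLATES = (
    "E(RHF) = {v:.6f}",
    "Sum of electronic and zero-point energies = {v:.6f}",
    "Gibbs free energy = {v:.6f} Hartree",
    "Zero-point correction = {u:.6f} (Hartree/Particle)",
    "Single point energy: {v:.8f} a.u.",
)

_HEADER_TEXT = "Supporting Information - Computational Details"

_LABEL_METHODS = ("B3LYP/6-31G(d)", "M06-2X/def2-TZVP", "CBS-QB3",
                  "B3LYP/6-311+G(d,p)")


def _noise_lines(rng: random.Random, count: int) -> list[str]:
    lines = []
    for _ in range(count):
        if rng.random() < 0.45:
            template = rng.choice(_ENERGY_TEMPLATES)
            lines.append(template.format(v=-rng.uniform(100.0, 700.0),
                                         u=rng.uniform(0.05, 0.3)))
        else:
            lines.append(rng.choice(_PROSE))
    return lines


def adversarial_noise_bank() -> list[tuple[str, bool]]:
    """Near-miss lines tagged ``(text, canonical parser accepts?)``.

    Covers the classic failure sources: too few numeric fields, energy
    statements with floats, serial-index rows that *are* line-level
    valid (block-level checks reject those), ragged decimals that are
    valid, and misaligned-but-valid rows.
    """
    return [
        ("0 1", False),                       # charge/multiplicity line
        ("1 2", False),                       # two fields only
        ("E = -115.2", False),
        ("E(RHF) = -115.123456", False),
        ("Gibbs free energy = -234.567", False),
        ("Total = 42", False),
        ("1 2 3 4", True),                    # serial row: valid line,
        ("2 1.0 2.0 3.0", True),              # rejected at block level
        ("N 0.1 -0.22 3.123456789", True),    # ragged decimals
        ("C   1.469881  -0.009020   0.000000", True),  # misaligned columns
        ("O 1.0e2 0.0 0.0", False),           # scientific notation
        ("Xx 1.0 2.0 3.0", False),            # unknown element
        ("C 1.0 2.0 three", False),           # non-numeric tail
        ("119 0.0 0.0 0.0", False),           # atomic number out of range
    ]


# ---------------------------------------------------------------------------
# Document generation
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """What to generate; defaults give a typical three-molecule document."""

    n_molecules: int = 3
    delimiter: str = "space"          # space | comma | tab
    decimals: int = 6                 # printed fractional digits (1..10)
    element_style: str = "symbol"     # symbol | atomic_number | mixed
    noise_between: tuple[int, int] = (1, 3)   # noise lines between blocks
    page_length: int | None = None    # lines per page; None = no pagination
    with_labels: bool = True
    serial_table: bool = False        # inject a serial-index numeric table


@dataclass
class ManifestMolecule:
    label: str | None
    name: str
    elements: list[str]       # canonical symbols
    tokens: list[str]         # first-column tokens as printed
    coord_texts: list[list[str]]   # exact numeric fields as printed
    lines: list[str]          # exact coordinate lines as printed


@dataclass
class FixtureManifest:
    """Everything the generator emitted, for exact-recovery checks."""

    seed: int
    delimiter: str
    decimals: int
    element_style: str
    molecules: list[ManifestMolecule]
    residual_lines: list[str]   # every emitted non-coordinate line, in order
    n_pages: int
    expected_blocks: int
    expected_atoms: int
    dropped_serial_lines: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _random_rotation(rng: random.Random) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = np.array([rng.gauss(0.0, 1.0) for _ in range(4)])
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


_COORD_LIMIT = 9.4  # keep every printed coordinate to one integer digit


def _place_molecule(rng: random.Random, mol: ToyMolecule) -> np.ndarray:
    coords = np.array(mol.coords) @ _random_rotation(rng).T
    shift = np.empty(3)
    for ax in range(3):
        lo = -_COORD_LIMIT - coords[:, ax].min()
        hi = _COORD_LIMIT - coords[:, ax].max()
        shift[ax] = rng.uniform(lo, hi)
    return coords + shift


_SEPARATORS = {"space": " ", "comma": ",", "tab": "\t"}


def _format_molecule(rng: random.Random, mol: ToyMolecule,
                     coords: np.ndarray, spec: FixtureSpec
                     ) -> ManifestMolecule:
    sep = _SEPARATORS[spec.delimiter]
    tokens, coord_texts, lines = [], [], []
    for el, (x, y, z) in zip(mol.elements, coords):
        if spec.element_style == "symbol":
            token = el
        elif spec.element_style == "atomic_number":
            token = str(SYMBOL_TO_Z[el])
        else:
            token = rng.choice([el, str(SYMBOL_TO_Z[el])])
        fields = [f"{v:.{spec.decimals}f}" for v in (x, y, z)]
        if spec.delimiter == "space":
            # emulate ragged column alignment with variable-width gaps
            gaps = [" " * rng.randint(1, 3) for _ in range(3)]
            line = token + gaps[0] + fields[0] + gaps[1] + fields[1] \
                + gaps[2] + fields[2]
        else:
            line = sep.join([token, *fields])
        tokens.append(token)
        coord_texts.append(fields)
        lines.append(line)
    return ManifestMolecule(label=None, name=mol.name,
                            elements=list(mol.elements), tokens=tokens,
                            coord_texts=coord_texts, lines=lines)


def generate_document(spec: FixtureSpec, seed: int
                      ) -> tuple[str, FixtureManifest]:
    """Emit a synthetic supplementary document and its manifest.

    Deterministic: the same spec and seed reproduce byte-identical text
    and manifest. Pages are separated by form feeds in the text form;
    when pagination is on, page-number footers (and, with three or more
    pages, a running header) are injected, so breaks landing inside a
    molecule exercise the healing rule.
    """
    if spec.n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    if spec.delimiter not in _SEPARATORS:
        raise ValueError(f"invalid delimiter: {spec.delimiter!r}")
    if not 1 <= spec.decimals <= 10:
        raise ValueError("decimals must be in 1..10")
    library = list(toy_molecule_library().values())
    longest = max(len(m.elements) for m in library)
    if spec.page_length is not None and spec.page_length < longest + 3:
        raise ValueError(
            f"page_length {spec.page_length} is shorter than the longest "
            f"molecule plus furniture ({longest + 3} lines)")
    rng = random.Random(seed)

    # body: (text, is_coordinate) pairs
    body: list[tuple[str, bool]] = []
    molecules: list[ManifestMolecule] = []
    body.append((rng.choice(_PROSE), False))
    body.append(("", False))
    dropped_serial = 0
    for k in range(spec.n_molecules):
        mol = rng.choice(library)
        placed = _place_molecule(rng, mol)
        record = _format_molecule(rng, mol, placed, spec)
        if spec.with_labels:
            record.label = (f"Molecule {k + 1}: {mol.name} "
                            f"({rng.choice(_LABEL_METHODS)})")
            body.append((record.label, False))
        for line in record.lines:
            body.append((line, True))
        molecules.append(record)
        for noise in _noise_lines(rng, rng.randint(*spec.noise_between)):
            body.append((noise, False))
        body.append(("", False))
    if spec.serial_table:
        # serial-index rows parse at line level but are dropped at block
        # level, so they end up in the residual text, not in any block
        body.append(("Table S1. Relative energies (kcal/mol).", False))
        rows = rng.randint(3, 5)
        for r in range(1, rows + 1):
            body.append((f"{r} {rng.uniform(-20, 20):.2f} "
                         f"{rng.uniform(-20, 20):.2f} "
                         f"{rng.uniform(0, 5):.2f}", False))
        dropped_serial = rows
        body.append(("", False))
    for noise in _noise_lines(rng, rng.randint(1, 3)):
        body.append((noise, False))

    # pagination
    if spec.page_length is None:
        pages = [body]
    else:
        n_pages = math.ceil(len(body) / spec.page_length) or 1
        with_header = n_pages >= _MIN_PAGES_FOR_HEADER
        pages = []
        for p in range(n_pages):
            chunk = body[p * spec.page_length:(p + 1) * spec.page_length]
            page: list[tuple[str, bool]] = []
            if with_header:
                page.append((_HEADER_TEXT, False))
            page.extend(chunk)
            page.append((f"S{p + 1}", False))
            pages.append(page)

    text = "\f".join("\n".join(t for t, _ in page) for page in pages)
    residual = [t for page in pages for t, is_coord in page if not is_coord]
    manifest = FixtureManifest(
        seed=seed,
        delimiter=spec.delimiter,
        decimals=spec.decimals,
        element_style=spec.element_style,
        molecules=molecules,
        residual_lines=residual,
        n_pages=len(pages),
        expected_blocks=len(molecules),
        expected_atoms=sum(len(m.elements) for m in molecules),
        dropped_serial_lines=dropped_serial,
    )
    return text, manifest


_MIN_PAGES_FOR_HEADER = 3


def render_fixture_pdf(text: str) -> bytes:
    """Render a generated fixture document as a single-column PDF.

    Blank lines are rendered as a single space so they survive text
    extraction (an empty string draws nothing); after
    :func:`molharvest.ingest.normalize_lines` the PDF and text paths
    yield identical lines.
    """
    pages = [[line if line else " " for line in segment.split("\n")]
             for segment in text.split("\f")]
    return _pdf.render_pdf(pages)
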