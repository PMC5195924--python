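"""Distance-based bond perception and geometric validation.

Connectivity is rebuilt from Cartesian coordinates alone: two atoms are
bonded when their separation does not exceed the sum of their covalent
radii plus a fixed tolerance (default 0.35 Angstrom, with boundary
equality counting as bonded). Bond order is uniformly single -- the
coordinates carry no order information and assigning it is out of
scope. The default radii are the Cordero et al. (2008) single-bond
covalent radii, which cover Z = 1..96; looking up an uncovered element
is an explicit error, never a silent default.

Indices in the public API (bond lists, angle/dihedral arguments,
geometry reports) are 1-based in block order, matching the connection
tables written downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .blocks import MoleculeBlock
from .patterns import AtomRecord

__all__ = [
    "DEFAULT_TOLERANCE",
    "UncoveredElementError",
    "DegenerateGeometryError",
    "CovalentRadiiTable",
    "BondMatrix",
    "GeometryReport",
    "interatomic_distance",
    "bond_cutoff",
    "perceive_bonds",
    "bond_angle",
    "dihedral_angle",
    "validate_geometry",
]

#: Tolerance added to the sum of covalent radii when deciding bonding (A).
DEFAULT_TOLERANCE = 0.35

#: Any pair closer than this is flagged as a steric clash (A).
CLASH_DISTANCE = 0.4

#: Maximum plausible coordination numbers used for hypervalency warnings.
_MAX_DEGREE = {"H": 1, "C": 4, "N": 4, "O": 3, "S": 6,
               "F": 1, "Cl": 1, "Br": 1, "I": 1, "At": 1}
_MAX_DEGREE_DEFAULT = 8


class UncoveredElementError(LookupError):
    """A radii table has no entry for the requested element."""

    def __init__(self, element: str, table_name: str):
        self.element = element
        super().__init__(
            f"element {element!r} is not covered by radii table "
            f"{table_name!r}")


class DegenerateGeometryError(ValueError):
    """Coincident or collinear points make an angle undefined."""


@dataclass(frozen=True)
class CovalentRadiiTable:
    """Named map from element symbol to covalent radius in Angstrom."""

    name: str
    radii: dict[str, float]

    def __post_init__(self):
        from .patterns import ELEMENTS
        for symbol, r in self.radii.items():
            if not (0.0 < r < 3.0):
                raise ValueError(
                    f"radius for {symbol} out of range (0, 3.0): {r}")
        missing = [s for s in ELEMENTS[:96] if s not in self.radii]
        if missing:
            raise ValueError(
                f"radii table {self.name!r} must cover Z=1..96; missing: "
                + ", ".join(missing))

    def radius(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            raise UncoveredElementError(element, self.name) from None

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "CovalentRadiiTable":
        """Load a two-column (symbol, radius in A) plain-text table."""
        radii: dict[str, float] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                symbol, value = line.split()
                radii[symbol] = float(value)
        return cls(name=name or str(path), radii=radii)

    @classmethod
    def cordero_2008(cls) -> "CovalentRadiiTable":
        """The packaged Cordero et al. (2008) single-bond radii."""
        ref = resources.files("molharvest.data").joinpath("cordero2008.txt")
        with resources.as_file(ref) as path:
            table = cls.from_file(path, name="cordero2008")
        return table


_DEFAULT_TABLE: CovalentRadiiTable | None = None


def default_radii_table() -> CovalentRadiiTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = CovalentRadiiTable.cordero_2008()
    return _DEFAULT_TABLE


@dataclass
class BondMatrix:
    """Symmetric 0/1 connectivity with per-bond distances.

    ``bonds`` holds ``(i, j, distance)`` with 1-based ``i < j`` in block
    order; ``adjacency`` is the equivalent n x n 0/1 matrix.
    """

    n: int
    adjacency: np.ndarray
    bonds: list[tuple[int, int, float]]
    tolerance: float

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def degree(self, i: int) -> int:
        """Number of bonds at 1-based atom index i."""
        return int(self.adjacency[i - 1].sum())

    def neighbors(self, i: int) -> list[int]:
        """1-based indices bonded to 1-based atom index i."""
        return [int(j) + 1 for j in np.flatnonzero(self.adjacency[i - 1])]


def interatomic_distance(a: AtomRecord, b: AtomRecord) -> float:
    """Euclidean distance between two atoms in Angstrom."""
    return math.dist(a.position, b.position)


def bond_cutoff(e1: str, e2: str,
                table: CovalentRadiiTable | None = None,
                tolerance: float = DEFAULT_TOLERANCE) -> float:
    """Bonding cutoff: r(e1) + r(e2) + tolerance, in Angstrom."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    table = table or default_radii_table()
    return table.radius(e1) + table.radius(e2) + tolerance


def perceive_bonds(block: MoleculeBlock,
                   table: CovalentRadiiTable | None = None,
                   tolerance: float = DEFAULT_TOLERANCE) -> BondMatrix:
    """All-pairs distance rule: bond iff distance <= cutoff.

    Boundary equality counts as bonded (only strictly larger distances
    are non-bonding). Every unordered pair is evaluated; there is no
    early exit or neighbor-list shortcut.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    table = table or default_radii_table()
    n = len(block.atoms)
    coords = np.array([a.position for a in block.atoms], dtype=float)
    coords = coords.reshape(n, 3)
    radii = np.array([table.radius(a.element) for a in block.atoms])
    delta = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((delta ** 2).sum(axis=2))
    cutoff = radii[:, None] + radii[None, :] + tolerance
    adjacency = (dist <= cutoff).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    ii, jj = np.nonzero(np.triu(adjacency, k=1))
    bonds = [(int(i) + 1, int(j) + 1, float(dist[i, j]))
             for i, j in zip(ii, jj)]
    return BondMatrix(n=n, adjacency=adjacency, bonds=bonds,
                      tolerance=tolerance)


def _vec(block: MoleculeBlock, i: int, j: int) -> np.ndarray:
    a = np.asarray(block.atoms[i - 1].position)
    b = np.asarray(block.atoms[j - 1].position)
    return b - a


def bond_angle(block: MoleculeBlock, i: int, j: int, k: int) -> float:
    """Angle i-j-k (apex j) in degrees, in [0, 180]. 1-based indices."""
    if len({i, j, k}) != 3:
        raise ValueError("indices must be distinct")
    u = _vec(block, j, i)
    v = _vec(block, j, k)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError(
            f"coincident atoms make angle ({i},{j},{k}) undefined")
    cosang = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def dihedral_angle(block: MoleculeBlock, i: int, j: int, k: int,
                   l: int) -> float:
    """Signed dihedral i-j-k-l in degrees, in (-180, 180].

    IUPAC sign convention: looking from j towards k, a positive angle
    is a clockwise rotation of the far bond relative to the near one
    (cis = 0).
    """
    if len({i, j, k, l}) != 4:
        raise ValueError("indices must be distinct")
    b1 = _vec(block, i, j)
    b2 = _vec(block, j, k)
    b3 = _vec(block, k, l)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm2 = np.linalg.norm(b2)
    if norm2 == 0.0 or np.linalg.norm(n1) == 0.0 \
            or np.linalg.norm(n2) == 0.0:
        raise DegenerateGeometryError(
            f"degenerate plane for dihedral ({i},{j},{k},{l})")
    m = np.cross(n1, b2 / norm2)
    angle = math.degrees(math.atan2(float(np.dot(m, n2)),
                                    float(np.dot(n1, n2))))
    if angle <= -180.0:
        angle += 360.0
    return angle


@dataclass
class GeometryReport:
    """All lengths, angles and dihedrals plus consistency warnings.

    Warnings are ``(kind, atom_indices)`` with kind one of
    ``isolated_atom``, ``atom_clash``, ``hypervalent``; indices are
    1-based.
    """

    bond_lengths: list[tuple[tuple[int, int], float]]
    bond_angles: list[tuple[tuple[int, int, int], float]]
    dihedrals: list[tuple[tuple[int, int, int, int], float]]
    warnings: list[tuple[str, tuple[int, ...]]] = field(default_factory=list)


def validate_geometry(block: MoleculeBlock,
                      bonds: BondMatrix) -> GeometryReport:
    """Enumerate geometric descriptors and flag inconsistencies.

    Angles are reported at every atom with two or more bonds (that atom
    as apex); dihedrals along every bonded 4-atom path. An atom with no
    bonds in a multi-atom block is flagged ``isolated_atom`` (typical
    pagination-fragment signal); any pair closer than 0.4 A is an
    ``atom_clash``; degrees beyond an element's plausible maximum are
    ``hypervalent``.
    """
    n = bonds.n
    lengths = [((i, j), d) for i, j, d in bonds.bonds]

    angles: list[tuple[tuple[int, int, int], float]] = []
    for c in range(1, n + 1):
        nbrs = bonds.neighbors(c)
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                try:
                    angles.append(((nbrs[a], c, nbrs[b]),
                                   bond_angle(block, nbrs[a], c, nbrs[b])))
                except DegenerateGeometryError:
                    pass  # coincident atoms are reported as clashes

    dihedrals: list[tuple[tuple[int, int, int, int], float]] = []
    for j, k, _ in bonds.bonds:
        for i in bonds.neighbors(j):
            if i == k:
                continue
            for l in bonds.neighbors(k):
                if l == j or l == i:
                    continue
                try:
                    dihedrals.append(((i, j, k, l),
                                      dihedral_angle(block, i, j, k, l)))
                except DegenerateGeometryError:
                    pass  # collinear path: torsion undefined

    warnings: list[tuple[str, tuple[int, ...]]] = []
    if n >= 2:
        for i in range(1, n + 1):
            if bonds.degree(i) == 0:
                warnings.append(("isolated_atom", (i,)))
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if interatomic_distance(block.atoms[i - 1],
                                    block.atoms[j - 1]) < CLASH_DISTANCE:
                warnings.append(("atom_clash", (i, j)))
    for i in range(1, n + 1):
        element = block.atoms[i - 1].element
        limit = _MAX_DEGREE.get(element, _MAX_DEGREE_DEFAULT)
        if bonds.degree(i) > limit:
            warnings.append(("hypervalent", (i,)))
    return GeometryReport(bond_lengths=lengths, bond_angles=angles,
                          dihedrals=dihedrals, warnings=warnings)
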