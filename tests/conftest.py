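import random

import pytest

from molharvest.blocks import MoleculeBlock
from molharvest.bonds import CovalentRadiiTable, default_radii_table
from molharvest.fixtures import toy_molecule_library
from molharvest.ingest import document_from_lines
from molharvest.patterns import AtomRecord


def make_block(elements, coords, block_id=1, tokens=None):
    """Build a MoleculeBlock directly from element symbols and positions."""
    tokens = tokens or list(elements)
    atoms = [
        AtomRecord(element=e, x=p[0], y=p[1], z=p[2], raw_first_token=t,
                   source=(1, i + 1))
        for i, (e, p, t) in enumerate(zip(elements, coords, tokens))
    ]
    return MoleculeBlock(block_id=block_id, atoms=atoms,
                         span=(atoms[0].source, atoms[-1].source))


def make_doc(*pages):
    """DocumentText from lists of line strings (one list per page)."""
    return document_from_lines([list(p) for p in pages])


def random_block(rng: random.Random, n_atoms=None):
    """Random block: 3-40 atoms from common organic elements in a 10 A box."""
    elements = ["H", "C", "N", "O", "S", "P", "F", "Cl"]
    n = n_atoms or rng.randint(3, 40)
    els = [rng.choice(elements) for _ in range(n)]
    coords = [(rng.uniform(-5, 5), rng.uniform(-5, 5), rng.uniform(-5, 5))
              for _ in range(n)]
    return make_block(els, coords)


def brute_force_bonds(block, table=None, tolerance=0.35):
    """Independent pairwise oracle: nested loops, no vectorization."""
    import math
    table = table or default_radii_table()
    bonds = set()
    atoms = block.atoms
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            d = math.sqrt((atoms[i].x - atoms[j].x) ** 2
                          + (atoms[i].y - atoms[j].y) ** 2
                          + (atoms[i].z - atoms[j].z) ** 2)
            cutoff = (table.radii[atoms[i].element]
                      + table.radii[atoms[j].element] + tolerance)
            if d <= cutoff:
                bonds.add((i + 1, j + 1))
    return bonds


@pytest.fixture(scope="session")
def radii_table() -> CovalentRadiiTable:
    return default_radii_table()


@pytest.fixture(scope="session")
def toy_library():
    return toy_molecule_library()


@pytest.fixture
def water_block(toy_library):
    water = toy_library["water"]
    return make_block(water.elements, water.coords)
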