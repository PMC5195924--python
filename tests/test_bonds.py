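"""Bond perception against independent oracles; geometry validation."""

import math
import random

import numpy as np
import pytest

from molharvest.bonds import (DEFAULT_TOLERANCE, CovalentRadiiTable,
                              DegenerateGeometryError,
                              UncoveredElementError, bond_angle,
                              bond_cutoff, dihedral_angle,
                              interatomic_distance, perceive_bonds,
                              validate_geometry)

from conftest import brute_force_bonds, make_block, random_block


class TestRadiiTable:
    def test_packaged_table_invariants(self, radii_table):
        assert radii_table.name == "cordero2008"
        assert len(radii_table.radii) >= 96
        assert all(0.0 < r < 3.0 for r in radii_table.radii.values())

    def test_reference_values(self, radii_table):
        assert radii_table.radius("H") == 0.31
        assert radii_table.radius("C") == 0.76
        assert radii_table.radius("O") == 0.66

    def test_uncovered_element_is_an_explicit_error(self, radii_table):
        with pytest.raises(UncoveredElementError, match="Cf"):
            radii_table.radius("Cf")

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError, match="must cover"):
            CovalentRadiiTable(name="tiny", radii={"H": 0.31})

    def test_user_table_from_file(self, tmp_path, radii_table):
        path = tmp_path / "radii.txt"
        path.write_text("".join(f"{s} {r}\n"
                                for s, r in radii_table.radii.items()))
        table = CovalentRadiiTable.from_file(path, name="copy")
        assert table.radius("S") == radii_table.radius("S")


class TestDistanceAndCutoff:
    @pytest.mark.parametrize("a,b,expected", [
        ((0, 0, 0), (1, 0, 0), 1.0),
        ((1, 2, 3), (1, 2, 3), 0.0),
        ((1, 2, 3), (4, 6, 3), 5.0),
    ])
    def test_euclidean(self, a, b, expected):
        block = make_block(["C", "C"], [a, b])
        d = interatomic_distance(block.atoms[0], block.atoms[1])
        assert d == pytest.approx(expected)
        assert d == interatomic_distance(block.atoms[1], block.atoms[0])

    def test_cutoffs(self, radii_table):
        assert bond_cutoff("C", "C", radii_table, 0.0) == pytest.approx(
            2 * 0.76)
        assert bond_cutoff("H", "H", radii_table) == pytest.approx(0.97)
        assert bond_cutoff("C", "O", radii_table) == pytest.approx(1.77)
        assert bond_cutoff("O", "C", radii_table) == bond_cutoff(
            "C", "O", radii_table)

    def test_negative_tolerance_rejected(self, radii_table):
        with pytest.raises(ValueError):
            bond_cutoff("C", "C", radii_table, -0.1)


class TestPerceiveBonds:
    def test_single_atom_has_no_bonds(self):
        m = perceive_bonds(make_block(["He"], [(0, 0, 0)]))
        assert m.bonds == [] and m.n == 1

    def test_water(self, water_block):
        m = perceive_bonds(water_block)
        assert {(i, j) for i, j, _ in m.bonds} == {(1, 2), (1, 3)}

    def test_distant_pair_unbonded(self):
        m = perceive_bonds(make_block(["He", "He"],
                                      [(0, 0, 0), (10, 0, 0)]))
        assert m.bonds == []

    def test_boundary_equality_is_bonded(self, radii_table):
        d = bond_cutoff("C", "C", radii_table)
        m = perceive_bonds(make_block(["C", "C"], [(0, 0, 0), (d, 0, 0)]))
        assert len(m.bonds) == 1
        m2 = perceive_bonds(make_block(["C", "C"],
                                       [(0, 0, 0), (d + 1e-9, 0, 0)]))
        assert m2.bonds == []

    def test_uncovered_element_propagates(self):
        with pytest.raises(UncoveredElementError, match="Bk"):
            perceive_bonds(make_block(["Bk", "C"],
                                      [(0, 0, 0), (1, 0, 0)]))

    def test_adjacency_matches_bond_list(self, water_block):
        m = perceive_bonds(water_block)
        assert (m.adjacency == m.adjacency.T).all()
        assert np.diag(m.adjacency).sum() == 0
        pairs = {(i, j) for i, j, _ in m.bonds}
        ii, jj = np.nonzero(np.triu(m.adjacency))
        assert {(int(i) + 1, int(j) + 1) for i, j in zip(ii, jj)} == pairs

    def test_oracle_equivalence_on_random_blocks(self, radii_table):
        """Vectorized perception equals an independent pairwise loop."""
        rng = random.Random(20210)
        for _ in range(120):
            block = random_block(rng)
            ours = {(i, j) for i, j, _ in
                    perceive_bonds(block, radii_table).bonds}
            assert ours == brute_force_bonds(block, radii_table)

    def test_tolerance_monotonicity(self, radii_table):
        rng = random.Random(4)
        for _ in range(25):
            block = random_block(rng)
            loose = {(i, j) for i, j, _ in
                     perceive_bonds(block, radii_table, 0.35).bonds}
            tight = {(i, j) for i, j, _ in
                     perceive_bonds(block, radii_table, 0.0).bonds}
            wider = {(i, j) for i, j, _ in
                     perceive_bonds(block, radii_table, 0.8).bonds}
            assert tight <= loose <= wider

    def test_permutation_equivariance(self, radii_table):
        rng = random.Random(99)
        block = random_block(rng, n_atoms=12)
        base = perceive_bonds(block, radii_table)
        perm = list(range(12))
        rng.shuffle(perm)
        permuted = make_block([block.atoms[p].element for p in perm],
                              [block.atoms[p].position for p in perm])
        inverse = {p: i for i, p in enumerate(perm)}
        expected = {tuple(sorted((inverse[i - 1] + 1, inverse[j - 1] + 1)))
                    for i, j, _ in base.bonds}
        got = {(i, j) for i, j, _ in
               perceive_bonds(permuted, radii_table).bonds}
        assert got == expected

    def test_connectivity_matches_rdkit_on_toy_library(self, toy_library):
        """Cross-toolkit check against rdkit's distance-based perception."""
        from rdkit import Chem
        from rdkit.Chem import rdDetermineBonds
        for mol in toy_library.values():
            block = make_block(mol.elements, mol.coords)
            ours = {(i, j) for i, j, _ in perceive_bonds(block).bonds}
            xyz = f"{len(mol.elements)}\n{mol.name}\n" + "\n".join(
                f"{e} {x:.6f} {y:.6f} {z:.6f}"
                for e, (x, y, z) in zip(mol.elements, mol.coords)) + "\n"
            rmol = Chem.MolFromXYZBlock(xyz)
            rdDetermineBonds.DetermineConnectivity(rmol)
            theirs = {tuple(sorted((b.GetBeginAtomIdx() + 1,
                                    b.GetEndAtomIdx() + 1)))
                      for b in rmol.GetBonds()}
            # no tolerance-difference exceptions needed for these geometries
            assert ours == theirs, mol.name


class TestAngles:
    def test_collinear_is_180(self):
        block = make_block(["C", "C", "C"],
                           [(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        assert bond_angle(block, 1, 2, 3) == pytest.approx(180.0)

    def test_right_angle(self):
        block = make_block(["C", "C", "C"],
                           [(1, 0, 0), (0, 0, 0), (0, 1, 0)])
        assert bond_angle(block, 1, 2, 3) == pytest.approx(90.0)

    def test_water_angle(self, water_block):
        assert bond_angle(water_block, 2, 1, 3) == pytest.approx(
            104.5, abs=0.1)

    def test_signed_dihedral_against_vector_algebra(self):
        pts = [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 0, 1)]
        block = make_block(["C"] * 4, pts)
        # independent construction with raw numpy vector algebra
        p = [np.array(v, dtype=float) for v in pts]
        b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        m = np.cross(n1, b2 / np.linalg.norm(b2))
        expected = math.degrees(math.atan2(m @ n2, n1 @ n2))
        assert expected == pytest.approx(-90.0)
        assert dihedral_angle(block, 1, 2, 3, 4) == pytest.approx(expected)

    def test_dihedral_sign_flips_with_mirror(self):
        pts = [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 0, -1)]
        block = make_block(["C"] * 4, pts)
        assert dihedral_angle(block, 1, 2, 3, 4) == pytest.approx(90.0)

    def test_degenerate_geometry_errors(self):
        block = make_block(["C", "C", "C"],
                           [(0, 0, 0), (0, 0, 0), (1, 0, 0)])
        with pytest.raises(DegenerateGeometryError):
            bond_angle(block, 1, 2, 3)
        collinear = make_block(["C"] * 4, [(0, 0, 0), (1, 0, 0),
                                           (2, 0, 0), (3, 0, 0)])
        with pytest.raises(DegenerateGeometryError):
            dihedral_angle(collinear, 1, 2, 3, 4)

    def test_indices_must_be_distinct(self):
        block = make_block(["C", "C", "C"],
                           [(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        with pytest.raises(ValueError):
            bond_angle(block, 1, 2, 1)


class TestValidateGeometry:
    def test_water_report(self, water_block):
        m = perceive_bonds(water_block)
        report = validate_geometry(water_block, m)
        assert len(report.bond_lengths) == 2
        assert len(report.bond_angles) == 1
        assert report.bond_angles[0][1] == pytest.approx(104.5, abs=0.1)
        assert report.dihedrals == []
        assert report.warnings == []

    def test_isolated_atom_flagged(self, toy_library):
        water = toy_library["water"]
        coords = list(water.coords) + [(15.0, 0.0, 0.0)]
        block = make_block(list(water.elements) + ["C"], coords)
        report = validate_geometry(block, perceive_bonds(block))
        assert ("isolated_atom", (4,)) in report.warnings

    def test_atom_clash_flagged(self):
        block = make_block(["C", "C"], [(0, 0, 0), (0.1, 0, 0)])
        report = validate_geometry(block, perceive_bonds(block))
        assert ("atom_clash", (1, 2)) in report.warnings

    def test_hypervalent_carbon_flagged(self):
        coords = [(0, 0, 0)] + [
            (math.cos(k * math.pi / 3), math.sin(k * math.pi / 3), 0.0)
            for k in range(6)]
        block = make_block(["C"] + ["H"] * 6, coords)
        report = validate_geometry(block, perceive_bonds(block))
        kinds = {k for k, _ in report.warnings}
        assert "hypervalent" in kinds

    def test_ethane_dihedral_count(self, toy_library):
        ethane = toy_library["ethane"]
        block = make_block(ethane.elements, ethane.coords)
        report = validate_geometry(block, perceive_bonds(block))
        # 3 H on each side of the central bond: 9 torsions across C-C
        torsions = [t for t in report.dihedrals
                    if t[0][1:3] in ((1, 2), (2, 1))]
        assert len(torsions) == 9

    def test_default_tolerance_constant(self):
        assert DEFAULT_TOLERANCE == 0.35
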