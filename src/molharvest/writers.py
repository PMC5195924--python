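"""Serialize extracted molecules into standard chemical file formats.

The output contract mirrors the classic three-file harvest: every
molecule in one multi-record SDF (MDL V2000 connection tables, order-1
bonds), one Gaussian job file per molecule, and plain-text reports for
the bond matrices and for the residual (non-molecular) document text.
An XYZ writer is included for viewers that want the minimal format.

All writers are deterministic: identical inputs give byte-identical
output (no timestamps). SDF coordinates use the format's canonical
four decimal places; GJF and XYZ keep eight, enough to round-trip the
precision these documents print.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .blocks import MoleculeBlock
from .bonds import BondMatrix
from .ingest import DocumentText

__all__ = [
    "OutputBundle",
    "write_sdf",
    "write_mol",
    "write_gjf",
    "write_xyz",
    "write_bond_matrix_text",
    "write_residual_text",
    "build_bundle",
    "write_bundle",
]

_V2000_ATOM_LIMIT = 999


class MolfileError(Exception):
    """A molecule cannot be represented in the requested format."""


def _title(block: MoleculeBlock) -> str:
    return block.label if block.label else f"Mol ID {block.block_id}"


def _mol_record(block: MoleculeBlock, bonds: BondMatrix) -> str:
    n = block.n_atoms
    if n > _V2000_ATOM_LIMIT:
        raise MolfileError(
            f"block {block.block_id} has {n} atoms; the V2000 connection "
            f"table is limited to {_V2000_ATOM_LIMIT}")
    # the "3D" dimensionality code sits at fixed columns 21-22
    lines = [_title(block), "  molharvest        3D", "",
             f"{n:3d}{bonds.n_bonds:3d}  0  0  0  0  0  0  0  0999 V2000"]
    for atom in block.atoms:
        lines.append(
            f"{atom.x:10.4f}{atom.y:10.4f}{atom.z:10.4f} "
            f"{atom.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j, _ in bonds.bonds:
        lines.append(f"{i:3d}{j:3d}  1  0")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def write_mol(block: MoleculeBlock, bonds: BondMatrix) -> str:
    """Single MDL MOL V2000 record (no ``$$$$`` terminator)."""
    return _mol_record(block, bonds)


def write_sdf(blocks: list[MoleculeBlock],
              bond_matrices: list[BondMatrix]) -> str:
    """Multi-record SDF: one V2000 record per block, in block order."""
    if len(blocks) != len(bond_matrices):
        raise ValueError("need exactly one bond matrix per block")
    records = [_mol_record(b, m) + "$$$$\n"
               for b, m in zip(blocks, bond_matrices)]
    return "".join(records)


def write_gjf(block: MoleculeBlock, route: str = "#", charge: int = 0,
              multiplicity: int = 1) -> str:
    """Gaussian job file: route, title, charge/multiplicity, geometry."""
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    lines = [route, "", _title(block), "", f"{charge} {multiplicity}"]
    for atom in block.atoms:
        lines.append(f"{atom.element:<2s} {atom.x:14.8f} {atom.y:14.8f} "
                     f"{atom.z:14.8f}")
    lines.append("")
    return "\n".join(lines) + "\n"


def write_xyz(blocks: list[MoleculeBlock]) -> str:
    """Concatenated XYZ records: count line, comment, atom lines."""
    parts = []
    for block in blocks:
        lines = [str(block.n_atoms), _title(block)]
        for atom in block.atoms:
            lines.append(f"{atom.element:<2s} {atom.x:14.8f} "
                         f"{atom.y:14.8f} {atom.z:14.8f}")
        parts.append("\n".join(lines) + "\n")
    return "".join(parts)


def write_bond_matrix_text(blocks: list[MoleculeBlock],
                           bond_matrices: list[BondMatrix]) -> str:
    """Human-readable per-molecule bond report."""
    if len(blocks) != len(bond_matrices):
        raise ValueError("need exactly one bond matrix per block")
    lines: list[str] = []
    for block, bonds in zip(blocks, bond_matrices):
        lines.append(f"Mol ID {block.block_id}  atoms={block.n_atoms}  "
                     f"bonds={bonds.n_bonds}")
        for i, j, d in bonds.bonds:
            lines.append(f"{i} {j} {block.atoms[i - 1].element} "
                         f"{block.atoms[j - 1].element} {d:.3f}")
    return "\n".join(lines) + "\n" if lines else ""


def write_residual_text(doc: DocumentText,
                        blocks: list[MoleculeBlock]) -> str:
    """Document lines not consumed into any block, with page markers."""
    consumed = {atom.source for block in blocks for atom in block.atoms}
    lines: list[str] = []
    for page in doc.pages:
        lines.append(f"--- page {page.number} ---")
        for i, text in enumerate(page.lines, start=1):
            if (page.number, i) not in consumed:
                lines.append(text)
    return "\n".join(lines) + "\n" if lines else ""


ALL_FORMATS = ("sdf", "gjf", "xyz", "bonds", "residual")


@dataclass
class OutputBundle:
    """The rendered output texts for one extraction run."""

    sdf: str | None
    gjf: list[tuple[int, str]]  # (block_id, text)
    xyz: str | None
    bond_matrix: str | None
    residual: str | None


def build_bundle(doc: DocumentText, blocks: list[MoleculeBlock],
                 bond_matrices: list[BondMatrix],
                 formats: tuple[str, ...] = ALL_FORMATS, *,
                 route: str = "#", charge: int = 0,
                 multiplicity: int = 1) -> OutputBundle:
    unknown = set(formats) - set(ALL_FORMATS)
    if unknown:
        raise ValueError(f"unknown formats: {sorted(unknown)}")
    if not formats:
        raise ValueError("formats subset must be non-empty")
    return OutputBundle(
        sdf=write_sdf(blocks, bond_matrices) if "sdf" in formats else None,
        gjf=[(b.block_id, write_gjf(b, route, charge, multiplicity))
             for b in blocks] if "gjf" in formats else [],
        xyz=write_xyz(blocks) if "xyz" in formats else None,
        bond_matrix=(write_bond_matrix_text(blocks, bond_matrices)
                     if "bonds" in formats else None),
        residual=(write_residual_text(doc, blocks)
                  if "residual" in formats else None),
    )


def write_bundle(bundle: OutputBundle, out_dir: str | Path,
                 stem: str) -> list[Path]:
    """Write a bundle to ``out_dir`` with the conventional file names."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, text: str) -> None:
        path = out_dir / name
        path.write_text(text, encoding="utf-8")
        written.append(path)

    if bundle.sdf is not None:
        emit(f"{stem}.sdf", bundle.sdf)
    for block_id, text in bundle.gjf:
        emit(f"{stem}_mol{block_id}.gjf", text)
    if bundle.xyz is not None:
        emit(f"{stem}.xyz", bundle.xyz)
    if bundle.bond_matrix is not None:
        emit(f"{stem}_bonds.txt", bundle.bond_matrix)
    if bundle.residual is not None:
        emit(f"{stem}_residual.txt", bundle.residual)
    return written
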