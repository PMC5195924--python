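# molharvest

Recover computable 3D molecules from the coordinate tables buried in
PDF supplementary-information files.

Computational chemistry articles routinely deposit optimized
geometries — one line per atom, element symbol (or atomic number)
followed by Cartesian x, y, z in ångströms — inside supplementary PDFs,
mixed with prose, energies, tables and page furniture. In that form
the structures cannot be fed back into any modelling program.
`molharvest` is for the researcher who wants those structures back: it
finds the coordinate lines, groups them into molecules (healing page
breaks that split a table in two), rebuilds covalent connectivity from
geometry alone, and writes ready-to-compute files.

## Method

- **Line recognition.** A line is an atomic-coordinate record when its
  first token is an element symbol or atomic number (Z ∈ 1..118) and it
  is followed by at least three fixed-decimal fields in one delimiter
  dialect (space, comma or tab; auto-detected by majority vote). Two
  legacy harvesting regular expressions for the space and comma
  dialects are shipped verbatim as a fidelity baseline
  (`--paper-pattern`).
- **Block assembly.** A molecule is a maximal run of coordinate lines.
  Blank lines, page numbers ("14", "S14", "Page 3") and running
  headers interrupting a run are healed (up to five in a row); any
  substantive text terminates it. Serial-index table rows
  (1, 2, 3, …) are rejected as numeric-table noise.
- **Bond perception.** Atoms *i*, *j* are bonded iff

  *d(i, j)* ≤ *r*(elementᵢ) + *r*(elementⱼ) + *t*,

  with Cordero (2008) covalent radii *r* and tolerance *t* = 0.35 Å by
  default; boundary equality counts as bonded, and all perceived bonds
  are single (coordinates carry no bond-order information). Bond
  lengths, angles and dihedrals are enumerated and checked for
  isolated atoms, steric clashes and hypervalent coordination.
- **Output.** Multi-record SDF (MDL V2000), one Gaussian job file per
  molecule, XYZ, a plain-text bond-matrix report, and the residual
  (non-molecular) text — deterministic, byte-stable files.

## Worked example

Generate a synthetic supplementary document (three molecules, rendered
both as text and PDF) and extract it:

```sh
$ molharvest fixture --out-dir . --molecules 3 --delimiter space --seed 42 --pdf
wrote fixture_seed42.txt (3 molecules, 11 atoms)
$ molharvest extract -i fixture_seed42.pdf --out-dir out
fixture_seed42.pdf: 3 molecule(s), 11 atom(s)
```

`out/fixture_seed42_bonds.txt` begins:

```
Mol ID 1  atoms=3  bonds=2
1 2 O H 0.957
1 3 O H 0.957
Mol ID 2  atoms=5  bonds=4
1 2 C H 1.090
...
```

Molecule 1 is a water: two O–H bonds of 0.957 Å were perceived from
the coordinates alone (0.957 ≤ r_O + r_H + 0.35 = 1.32 Å, while the
H···H separation of 1.51 Å exceeds its 0.97 Å cutoff). The SDF record
carries the same connectivity as an MDL connection table:

```
Molecule 1: water (M06-2X/def2-TZVP)
  molharvest        3D

  3  2  0  0  0  0  0  0  0  0999 V2000
    3.5112    6.7752   -7.7843 O   0  0  ...
    2.9259    7.5326   -7.7927 H   0  0  ...
    2.9631    6.0520   -7.4799 H   0  0  ...
  1  2  1  0
  1  3  1  0
M  END
```

and `out/fixture_seed42_report.json` records the audit: 27 document
lines, 11 coordinate lines, 3 blocks, 11 atoms, no warnings. The
residual file holds the other 16 lines (titles, energies, page
furniture) for downstream text mining.

The same pipeline is available as a library:

```python
from molharvest import (read_document, normalize_lines, detect_delimiter,
                        segment_blocks, perceive_bonds, write_sdf)

doc = normalize_lines(read_document("supporting_info.pdf"))
delim = detect_delimiter(doc)
blocks = segment_blocks(doc, delim)
sdf = write_sdf(blocks, [perceive_bonds(b) for b in blocks])
```

Encrypted or structurally unusual PDFs raise an error that points at
the standard workaround: save the document as plain text and re-run
with `--kind text`.

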