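# Methods

This note documents the models, rules and numerical choices behind
`molharvest`, what the synthetic-document generator does and does not
emulate, and the known limitations.

## Problem model

A supplementary document is modelled as ordered pages of ordered text
lines; every downstream object (atom record, molecule block) keeps a
`(page, line)` pointer back into that structure, which is what makes
the residual-text and conservation audits exact. Two input paths
produce the same structure: plain text (form feeds delimit pages) and
PDF.

### PDF handling

The PDF reader and the fixture renderer are implemented in-package on
top of stdlib `zlib`. The reader covers the class of documents this
tool targets: single-column pages whose content streams are
uncompressed or Flate-compressed, with standard one-byte string
encodings. It interprets the text-positioning operators (`Td`, `TD`,
`Tm`, `T*`, `TL`, `'`, `"`) and show operators (`Tj`, `TJ`), clusters
text runs by baseline (2-unit tolerance) and orders lines top-to-bottom.
Out of scope, by design: encryption, cross-reference/object streams
(PDF 1.5 object compression), CID/CMap fonts, and multi-column layout.
All of these raise a typed error whose message points at the
established fallback — save the PDF as plain text and use the text
path. The fallback is a first-class input, not a degraded mode.

### Character normalization

PDF extractors commonly emit U+2212 minus signs, non-breaking spaces
and typographic dashes. Normalization maps every Unicode `Zs` space
(except the tab, which carries delimiter information) to ASCII space
and every dash variant to `-`, then strips trailing whitespace. It is
idempotent and preserves line addressing. Ligature repair and
dehyphenation are deliberately not attempted: they cannot occur inside
numeric coordinate lines.

## Coordinate-line grammar

The canonical parser accepts a line iff: first token normalizes to an
element (alphabetic symbol, case-insensitive, or all-digit atomic
number 1..118; mixed tokens rejected), followed by ≥ 3 numeric fields
(optional sign, digits, optionally a decimal point with 1–10
fractional digits), with any extra trailing fields also numeric.
Dialects: space (runs of spaces collapse; a leading space disqualifies
the line, since coordinate rows start flush left), comma (spaces
around commas tolerated), tab. Scientific notation is rejected by
default (an `allow_scientific` switch accepts `1.0e2`/`1.0D2`): these
documents print fixed-decimal coordinates, and permitting exponents
would admit energy values. Coordinates must be finite and < 10⁶ Å in
magnitude. Classification is total — no line ever raises.

Two *legacy reference expressions* for the space and comma dialects
are shipped byte-for-byte and evaluated with anchored full-line
semantics. Their permissive constructs (`.{1,2}` where a sign/digit
class was presumably meant, a `.{1,}` tail) are intentionally not
repaired: they are a fidelity baseline, not the production parser. One
consequence, verified by test: they can only match coordinates with a
single integer digit, so they cover the small, origin-centred
molecules these documents contain but not arbitrary translations. The
canonical parser is kept *no more permissive* than the reference
expression of the same dialect on well-formed fixture lines (a tested
subset property); its extra strictness (exactly-typed numeric fields)
is what rejects near-miss noise the wildcards would admit.

Delimiter auto-detection parses every line under each dialect and
takes the majority, with ties broken space > comma > tab (space is the
most common dialect in practice and the safest default at zero).

## Block assembly

A molecule block is a maximal run of coordinate lines. The healing
rule for pagination: a run survives interruptions that are *ignorable*
— empty lines, page-number-like lines, or lines recurring on ≥ 3
distinct pages (running headers/footers) — as long as no more than 5
accumulate before coordinates resume; any other line terminates the
block. Choices made where the behaviour was genuinely open:

- **Page-number rule.** Bare integers are too narrow: supplementary
  documents number pages "S14", "A-7", "Page 3". The rule is a short
  optional alphabetic tag (≤ 4 letters) plus a 1–4 digit number. Cost:
  a bare label like "TS-1" is also treated as page furniture; labels
  with any annotation ("TS-1 (B3LYP/6-31G*)") are unaffected.
- **Resume window of 5** comfortably covers footer + header (+ blank)
  at a break while keeping distinct adjacent tables separate; it is a
  module constant.
- **Serial-index rejection.** A run whose first-column tokens are
  exactly 1, 2, 3, … is a numeric table, not a molecule (H–He–Li–…
  in that order is chemically implausible); it is dropped with a
  warning. Atomic-number columns in any other order are unaffected.
- **min_atoms = 2 by default**: a lone "coordinate" line is
  indistinguishable from table noise; genuinely monoatomic species can
  be recovered with `--min-atoms 1`.
- Two molecules printed back-to-back with no separator at all cannot
  be split — there is no signal in the text — and are out of scope.

Labels: the nearest preceding non-empty, non-coordinate, non-ignorable
line within 3 lines of the block start, truncated to 80 characters.

## Bond perception

Bond iff d ≤ r₁ + r₂ + t, evaluated over all pairs with no early
exit; boundary equality is bonded (only strictly larger separations
are non-bonding). Defaults: Cordero et al. (2008) single-bond covalent
radii (packaged as a two-column text file, Z = 1..96, sp³ carbon,
low-spin Mn/Fe/Co; user tables pluggable in the same format) and
t = 0.35 Å. One radius per element — no hybridization-specific values;
the tolerance absorbs that variation. An element outside the table is
an explicit error naming the element, never a silent default. All
bonds have order 1: distance data cannot distinguish bond orders, and
order assignment (e.g. Wiberg-type QM measures) is a non-goal.

Geometry validation enumerates bond lengths, angles at every atom of
degree ≥ 2 (that atom as apex), and dihedrals along bonded 4-paths,
using standard vector formulas; dihedrals are signed per the IUPAC
convention (cis = 0, range (−180°, 180°]) via the atan2 form, which is
numerically stable near 0° and 180°. Degenerate configurations
(coincident atoms, collinear torsion axes) raise a typed error in the
single-value functions and are skipped during bulk enumeration (the
coincident-atom case is already reported as a clash). Warnings:
`isolated_atom` (degree 0 in a block of ≥ 2 atoms — the typical
signature of a pagination fragment), `atom_clash` (< 0.4 Å),
`hypervalent` (degree above H:1, C:4, N:4, O:3, S:6, halogens:1,
others:8).

## Output formats

SDF/MOL V2000 with 4-decimal coordinates (the format's canonical
precision) and order-1 bonds; V3000 is not emitted, so blocks above
999 atoms are an explicit error. GJF (route `#`, charge 0,
multiplicity 1 by default) and XYZ print 8 decimals, enough to
round-trip the highest precision these documents print; round-trip
error through the canonical parser is 0 by construction and asserted
at ≤ 10⁻⁸ Å. No timestamps anywhere: identical inputs give
byte-identical files. One GJF per molecule. The residual file contains
every line not consumed into a block, in order, under `--- page N ---`
markers, so residual + consumed = total holds line-for-line.

## Synthetic documents

The generator emulates the structure of real supplementary files:
labelled coordinate tables in all three dialects and all three
element-column styles (symbols, atomic numbers, mixed), 1–10 printed
decimals, interleaved prose and energy lines, optional serial-index
tables, pagination with page-number footers and (on ≥ 3 pages)
running headers, and page breaks that may fall mid-molecule. Noise
vocabulary is synthesized from the content classes seen in real
supplements, not copied from copyrighted documents. Everything emitted
is recorded in a manifest (exact coordinate strings included), and
generation is byte-deterministic under a seed.

Coordinates are confined to |v| ≤ 9.4 Å — realistic for origin-centred
small molecules and within reach of the legacy expressions' one
integer digit. Toy geometries (water, methane, ethane, benzene,
dimethyl sulfide) are idealized from standard bond lengths and angles,
not DFT-optimized.

What the fixtures do *not* emulate — and therefore what passing tests
do not demonstrate: publisher-specific PDF typography, multi-column
layouts, scanned/rasterized pages, coordinate tables with > 1 integer
digit or scientific notation, and adjacent tables with no separator.
Performance on real supplements can be worse than on fixtures for
exactly these reasons.

## Problem sizes in the standard checks

The acceptance checks run 50 generated documents (2–4 molecules each)
for recovery and conservation, 120 random 3–40-atom blocks against a
brute-force pairwise bonding oracle (plus tolerance-monotonicity and
permutation-equivariance spot checks), and ≥ 1000 generated lines for
the reference-pattern subset property; the whole suite and the
acceptance script each complete in seconds. Larger sweeps change
nothing qualitatively: every check is exact, not statistical.

## Known limitations

- Molecule boundaries inside an unbroken coordinate run are
  undetectable.
- Bond orders, aromaticity, formal charges and non-covalent contacts
  are out of scope.
- The covalent-radius + 0.35 Å rule over-connects severely distorted
  geometries (e.g. transition states with forming bonds near the
  cutoff) and under-connects unusually long bonds; the tolerance is a
  single global knob (`--tolerance`).
- A bare alphanumeric label ("TS-1") directly above a block is
  mistaken for page furniture and not attached as the label.
- The PDF reader targets simple single-column documents; anything else
  must go through the text-export fallback.
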