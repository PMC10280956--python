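# Methods

## Conversion model

`cif2pdb` converts one mmCIF data block into legacy PDB output in four
stages, each a module:

1. **reader** — tokenizes CIF 1.1 syntax (comments, single/double quotes
   with the closing-quote-before-whitespace rule, column-1 semicolon
   blocks, case-insensitive `data_`/`loop_`/`stop_`) and materializes only
   the wanted categories. Every value is kept as its original string,
   including the null markers `.` and `?`.
2. **model** — normalizes the tables into a typed `StructureDoc`. Author
   identifiers (`auth_atom_id`, `auth_comp_id`, `auth_asym_id`,
   `auth_seq_id`) are preferred over `label_*` with fallback, because
   legacy PDB files carry author numbering. Coordinates are validated as
   decimal numbers but stored as the source strings.
3. **bundle** — partitions chains into output files under the legacy
   limits and owns the mapping file and TAR archive.
4. **writer** — renders the fixed-width records.

The governing invariant is *string fidelity*: any numeric string that fits
its column range is emitted unchanged, so slicing the output at the
documented columns returns the deposited text. The only sanctioned
string→number conversions are (a) ANISOU, where the format itself demands
U values as integers scaled by 10⁴ from the Å² decimals mmCIF stores, and
(b) the fallback in `pad_field` when a value is wider than its field, which
reduces decimal places with round-half-even (chosen for platform-stable
reproducibility) until the value fits.

## Bundle planning

A legacy file holds at most 99,999 serial numbers and 62 distinct chain
IDs. `TER` records consume serials, so each polymer chain contributes one
TER per model to the budget; a chain counts as polymer when any of its
atoms is in the `ATOM` group. Chains are packed greedily in input order: a
chain joins the current file unless it would exceed either limit.

Per file, chain IDs are assigned by walking chains in order: a chain keeps
its own ID when it is a single character from the pool `A–Z a–z 0–9` and
still free, otherwise it takes the first unused pool symbol. The pool
order and the keep-own-ID policy are this package's choice (made for
readability and determinism); the bundle convention itself fixes only the
62-symbol alphabet, so member-by-member agreement with archived bundles is
not a goal — the mapping file is the contract.

A chain that alone exceeds the serial budget is either split at residue
boundaries into consecutive files (residues are never divided) or, on
request, written into a single file whose serials wrap back to 1 after
99,999. Atom serials restart at 1 in every file.

The TAR archive is POSIX ustar written directly: fixed `mtime` 0,
checksum computed with the checksum field as spaces, and no padding beyond
the trailing two zero blocks. The standard-library `tarfile` writer pads
archives to 10 KiB records, which both bloats small bundles and is
unnecessary for reproducibility, so the 30-line header encoder is local;
`tarfile` serves as the reading oracle in tests.

## Record-level choices

* **CRYST1/SCALE.** `SCALE1–3` carry the fractionalization matrix
  recomputed from `_cell` (upper-triangular form; see the docstring of
  `compute_scale_matrix`). When no usable cell exists the conventional
  placeholder cell (1 Å cube, 90° angles, `P 1`, Z=1) is written and the
  SCALE matrix is the identity. A cell whose angles give non-positive
  volume is rejected as degenerate. CRYST1 lengths are normalized to 3
  decimals and angles to 2, the fixed precision the record conventionally
  carries.
* **Atom names.** A name of up to 3 characters belonging to a one-letter
  element starts at column 14 (`" CA "` for the α-carbon); two-letter
  elements and 4-character names start at column 13 (`"CA  "` for
  calcium). This is standard PDB practice, inferred from the element field.
* **Residue-number overflow.** Numbers to 9,999 are right-justified in
  columns 23–26 with the insertion code at 27; 5-digit numbers occupy
  23–27 and the insertion code is discarded with a warning (the encoding
  stays injective in each regime). Negative numbers to −999 right-justify
  in 23–26.
* **Long residue names** map to `01`…`99`, `DRG`, `INH`, `LIG` in that
  fixed order, first-come first-served, stable within a conversion and
  reported in the log; the 103rd distinct long name is a fatal error.
* **Emitted records** are HEADER, AUTHOR, JRNL (AUTH/TITL/REF/REFN/
  PMID/DOI), DBREF and SEQRES (both opt-in), CRYST1, SCALE1–3,
  ATOM/HETATM, ANISOU, TER, MODEL/ENDMDL, END. TITLE/KEYWDS/REMARK/HETNAM
  are not written; SHEET/HELIX/SSBOND/CONECT are out of scope by design
  (connectivity needs unique serials, which oversized structures lack).
* Only the first `data_` block is read; PDB-distributed files have one.
* The deposition date comes from
  `_pdbx_database_status.recvd_initial_deposition_date` when present
  (read opportunistically; otherwise the HEADER date is blank), reformatted
  to `DD-MMM-YY`. Only the `primary` citation (or the first row) becomes
  JRNL. Entry IDs that are not exactly 4 characters leave the HEADER
  idCode blank, logged, since columns 63–66 cannot hold them.

## Synthetic data

`cif2pdb.fixtures` generates deterministic mmCIF files: chains of
requested count and ID length, atoms distributed over residues, optional
unit cell, citation (with quoted and semicolon-delimited values, to
exercise the tokenizer), anisotropic records, sequences, database
references, multiple models, 5-digit residue numbers and over-long residue
names. Coordinates are generated *as strings* with 3 decimals drawn from a
seeded generator, so fidelity tests compare output columns to source text
exactly. Default magnitudes (coordinates within ±1000 Å, B-factors 0–100,
occupancy 1.00, cell edges 20–200 Å with angles 75–105°) are typical of
deposited structures.

What the generator does not emulate: physical geometry (atoms are uniform
random points), alternate conformations, heterogeneous ligands mixed into
polymer chains, microheterogeneity in sequences, and the full breadth of
real-world metadata. Passing tests therefore demonstrate format and
accounting correctness — limits, column layout, fidelity, determinism —
not chemical plausibility of inputs.

Test problem sizes: the serial-limit check uses 10 chains × 25,000 atoms
(250,000 atoms, four bundle files), the chain-limit check 70 chains × 100
atoms; fidelity and parser-equivalence suites each run 100 varied small
structures, and the SCALE identity property samples 1,000 random valid
cells against an independently constructed orthogonalization matrix
(agreement to 1e-9).

## Known limitations

* CIF 2.0 syntax (triple-quoted strings, lists) and dictionary validation
  are out of scope; writing mmCIF is out of scope.
* `_atom_sites` fractionalization matrices present in the input are
  ignored; SCALE is always recomputed from `_cell`, which keeps the output
  self-consistent but can differ in the last digit from a deposited
  matrix.
* DBREF sequence ranges wider than 4 digits cannot be represented in the
  record's columns.
* Phenix-style and single-file output refuse structures over 99,999
  serials unless duplicated serials are requested; bundle style is the
  general path.
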