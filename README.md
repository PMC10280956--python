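# cif2pdb

Faithful conversion of mmCIF (PDBx/mmCIF) structure files to the legacy
PDB format, including **Best Effort/Minimal bundle** output for structures
that exceed the format's hard limits.

## The problem

mmCIF is the official deposition format of the Protein Data Bank: a
whitespace-separated tabular text format whose fields have unlimited
width. The legacy PDB format, still the only input many structural
bioinformatics tools accept, is fixed-width: an atom serial number gets 5
columns and a chain identifier gets 1 column (column 22), capping a file
at 99,999 atoms and 62 chains. Large complexes — ribosomes, viral capsids,
structures with three-character chain IDs — simply do not fit.

The Best Effort/Minimal convention solves this by splitting one structure
into several PDB files, each within the atom and chain limits, remapping
every original chain ID onto a single character per file, and shipping the
members plus a chain-ID mapping file in one TAR archive. `cif2pdb`
implements that convention as a library and command-line tool:

* **String-preserving numerics.** Residue numbers, coordinates, occupancies
  and B-factors are read as strings and padded into their fixed-width
  columns without ever being converted to `int`/`float` and back — the
  output reproduces the deposited text exactly (and the conversion avoids
  needless numeric formatting work).
* **Chain handling.** Bundle output maps any chain ID (any length) onto the
  62-symbol pool `A–Z a–z 0–9` per file; Phenix-style output instead keeps
  two-character chain IDs by using the normally unused column 21 next to
  column 22.
* **Overflow conventions.** Residue numbers up to 99,999 are written with
  the 5th digit in column 27 (the insertion-code column); residue names
  longer than 3 characters map onto the reserved chemical component IDs
  `01`–`99`, `DRG`, `INH`, `LIG`, which are never assigned to real
  components. A single chain larger than 99,999 atoms is either split at
  residue boundaries across consecutive files or written with duplicated
  (wrapped) serial numbers — the user chooses.
* Record coverage: `HEADER`, `AUTHOR`, `JRNL`, `CRYST1`, `SCALE1–3`
  (the crystallographic fractionalization matrix recomputed from the unit
  cell), `ATOM`/`HETATM`, `ANISOU`, `TER`, `MODEL`/`ENDMDL`, and optionally
  `SEQRES` and `DBREF`. Bond records (`SSBOND`, `CONECT`) are deliberately
  not produced: they require globally unique atom serials, which a
  \>99,999-atom structure cannot have.

The converter has no runtime dependencies outside the Python standard
library. Gzip-compressed input is detected by magic bytes and decompressed
transparently.

## Worked example

Generate a small synthetic structure with three-character chain IDs (the
`cif2pdb.fixtures` module makes deterministic test structures) and convert
it:

```sh
python -c "
from cif2pdb.fixtures import FixtureSpec, write_cif
write_cif('demo.cif', FixtureSpec(n_chains=3, atoms_per_chain=8,
          chain_id_len=3, residues_per_chain=2, with_cell=True, seed=7))"
cif2pdb demo.cif -v --prefix demo
```

which logs

```
INFO wrote demo-pdb-bundle1.pdb (3 chains)
INFO   chain AAA -> A
INFO   chain AAB -> B
INFO   chain AAC -> C
INFO wrote demo-chain-id-mapping.txt
INFO wrote demo-pdb-bundle.tar
INFO conversion finished: 3 file(s)
```

The three chains fit one bundle member, so the bundle has a single PDB
file; its chain IDs `AAA`/`AAB`/`AAC` became `A`/`B`/`C`, recorded in
`demo-chain-id-mapping.txt`:

```
demo-pdb-bundle1.pdb:
    New chain ID    Original chain ID
    A               AAA
    B               AAB
    C               AAC
```

The PDB member starts with the title section and the unit cell, then the
coordinates — note the `CRYST1` cell constants and every coordinate string
carried over verbatim from the mmCIF input:

```
HEADER    SYNTHETIC BENCHMARK                     20-JUN-23   9SYN
AUTHOR    Doe, J.,Roe, Q.R.
CRYST1   78.290   47.153  137.168  77.17  91.08  85.97 P 1           4
SCALE1      0.012773 -0.000900  0.000454        0.00000
SCALE2      0.000000  0.021260 -0.004886        0.00000
SCALE3      0.000000  0.000000  0.007482        0.00000
ATOM      1  N   ALA A   1     -36.200 458.179 -58.754  1.00 43.36           N
ATOM      2  CA  ALA A   1     -23.158  -0.215 366.971  1.00 82.68           C
```

Other styles: `--style phenix` keeps two-character chain IDs in columns
21–22 in a single file; `--style single` writes one plain PDB file for
structures already within the legacy limits. `--seqres`/`--dbref` opt into
sequence and database-reference records; `--chain-overflow dup` selects
duplicated serials instead of chain splitting.

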